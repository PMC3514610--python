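"""Greedy, length-sorted unsupervised priming of bins under the calibrated model.

Contigs are processed from longest to shortest.  The longest contig seeds the
first bin; each subsequent contig is scored against every existing bin's
length-weighted mean vector and joins the highest-scoring bin whose score
reaches the confidence threshold for the contig's length, updating that bin's
mean.  Contigs that match no bin seed a new one only if they are at least
``min_seed_length`` long (short contigs approximate their source genome's
composition too poorly to anchor a bin).  The whole procedure is run once per
confidence level (90 / 95 / 98 % recall).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import CONFIDENCES, CalibrationTables, log_probability
from .tetra import N_CLASSES, FrequencyVector, frequency_vector

log = logging.getLogger(__name__)

DEFAULT_MIN_SEED_LENGTH = 1000


@dataclass
class Bin:
    """A growing bin with an incrementally maintained length-weighted mean."""

    id: int
    members: list = field(default_factory=list)          # contig ids, join order
    member_lengths: list = field(default_factory=list)
    total_length: int = 0
    mean_values: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    matched_windows: int = 0
    coverage_values: list = field(default_factory=list)
    profile: object = None

    @property
    def mean_vector(self) -> FrequencyVector:
        return FrequencyVector(values=self.mean_values, matched_windows=self.matched_windows)

    def add(self, contig, vector: FrequencyVector) -> None:
        w_old = self.total_length
        w_new = contig.length
        self.mean_values = (self.mean_values * w_old + vector.values * w_new) / (w_old + w_new)
        self.total_length += w_new
        self.matched_windows += vector.matched_windows
        self.members.append(contig.id)
        self.member_lengths.append(contig.length)
        self.coverage_values.append(contig.coverage)


@dataclass
class BinningResult:
    confidence: int
    bins: list
    unassigned: list                     # contig ids
    scores: dict = field(default_factory=dict)   # contig id -> (bin id, score)
    forced: set = field(default_factory=set)     # contig ids placed by --force-assign

    def assignment(self) -> dict:
        """contig id -> bin id for all binned contigs."""
        out = {}
        for b in self.bins:
            for cid in b.members:
                out[cid] = b.id
        return out


def greedy_bin(contigs, tables: CalibrationTables, confidence: int,
               min_seed_length: int = DEFAULT_MIN_SEED_LENGTH,
               force_assign: bool = False, vectors: dict | None = None) -> BinningResult:
    """Run the greedy priming pass at one confidence level.

    ``vectors`` may supply precomputed frequency vectors keyed by contig id.
    Deterministic: contigs are sorted by decreasing length with ties broken by
    id, and equal scores resolve to the lowest bin id (earliest seeded).
    """
    if confidence not in CONFIDENCES:
        raise ValueError(f"confidence must be one of {CONFIDENCES}")
    order = sorted(contigs, key=lambda c: (-c.length, c.id))
    sigma_table = tables.sigma_table
    bins: list[Bin] = []
    unassigned: list[str] = []
    scores: dict = {}
    forced: set = set()

    for contig in order:
        vec = vectors.get(contig.id) if vectors else None
        if vec is None:
            vec = frequency_vector(contig.seq)
        if not vec.defined:
            log.warning("contig %s has no valid tetranucleotide window; left unassigned",
                        contig.id)
            unassigned.append(contig.id)
            continue
        thr = tables.threshold(confidence, contig.length)
        best_bin = None
        best_score = -np.inf
        for b in bins:
            score, aborted = log_probability(vec, b.mean_vector, contig.length,
                                             sigma_table, abort_below=thr)
            if not aborted and score >= thr and score > best_score:
                best_bin, best_score = b, score
        if best_bin is not None:
            best_bin.add(contig, vec)
            scores[contig.id] = (best_bin.id, best_score)
        elif contig.length >= min_seed_length or not bins:
            new = Bin(id=len(bins) + 1)
            new.add(contig, vec)
            bins.append(new)
            scores[contig.id] = (new.id, np.nan)
        elif force_assign:
            # rescore without abort: the best bin is wanted even below threshold
            best_any_bin = None
            best_any_score = -np.inf
            for b in bins:
                score, _ = log_probability(vec, b.mean_vector, contig.length,
                                           sigma_table)
                if score > best_any_score:
                    best_any_bin, best_any_score = b, score
            # placed in the best-scoring bin regardless of threshold; the bin
            # mean is deliberately not updated for forced members
            best_any_bin.members.append(contig.id)
            best_any_bin.member_lengths.append(contig.length)
            best_any_bin.total_length += contig.length
            best_any_bin.coverage_values.append(contig.coverage)
            scores[contig.id] = (best_any_bin.id, best_any_score)
            forced.add(contig.id)
        else:
            unassigned.append(contig.id)
    return BinningResult(confidence=confidence, bins=bins, unassigned=unassigned,
                         scores=scores, forced=forced)


def run_all_confidences(contigs, tables: CalibrationTables,
                        min_seed_length: int = DEFAULT_MIN_SEED_LENGTH,
                        force_assign: bool = False) -> dict:
    """Three independent greedy passes, one per confidence level."""
    vectors = {c.id: frequency_vector(c.seq) for c in contigs}
    return {conf: greedy_bin(contigs, tables, conf, min_seed_length=min_seed_length,
                             force_assign=force_assign, vectors=vectors)
            for conf in CONFIDENCES}


@dataclass
class PartitionEvaluation:
    bin_majority: dict        # bin id -> majority source id
    bin_accuracy: dict        # bin id -> % correctly binned nucleotides
    source_recall: dict       # source id -> % of its nucleotides in its bin
    overall_accuracy: float   # % over all binned nucleotides


def evaluate_partition(result: BinningResult, truth: dict,
                       lengths: dict | None = None) -> PartitionEvaluation:
    """Nucleotide-weighted accuracy per bin and recall per source.

    Each bin is matched to the source contributing the most nucleotides to it;
    accuracy is correct nucleotides over bin nucleotides (x100).  Each source
    is matched to the bin holding most of its nucleotides; recall is that
    bin's share of the source's total nucleotides (x100).  When ``lengths``
    (contig id -> length) is given, unassigned contigs count toward source
    totals; otherwise recall is relative to the binned portion.
    """
    bin_majority: dict = {}
    bin_accuracy: dict = {}
    source_in_bin: dict = {}   # (source, bin) -> nucleotides
    correct_total = 0
    binned_total = 0
    for b in result.bins:
        if not b.members:
            continue
        by_source: dict = {}
        for cid, clen in zip(b.members, b.member_lengths):
            src = truth[cid]
            by_source[src] = by_source.get(src, 0) + clen
            source_in_bin[(src, b.id)] = source_in_bin.get((src, b.id), 0) + clen
        major = max(by_source, key=lambda s: (by_source[s], s))
        bin_nt = sum(by_source.values())
        bin_majority[b.id] = major
        bin_accuracy[b.id] = by_source[major] / bin_nt * 100.0
        correct_total += by_source[major]
        binned_total += bin_nt
    grand_total: dict = {}
    for b in result.bins:
        for cid, clen in zip(b.members, b.member_lengths):
            grand_total[truth[cid]] = grand_total.get(truth[cid], 0) + clen
    if lengths is not None:
        for cid in result.unassigned:
            src = truth[cid]
            grand_total[src] = grand_total.get(src, 0) + lengths[cid]
    source_recall: dict = {}
    for src in grand_total:
        best_bin = None
        best_nt = -1
        for b in result.bins:
            nt = source_in_bin.get((src, b.id), 0)
            if nt > best_nt:
                best_nt, best_bin = nt, b.id
        total = grand_total[src]
        source_recall[src] = (best_nt / total * 100.0) if total > 0 else 0.0
    overall = correct_total / binned_total * 100.0 if binned_total else 0.0
    return PartitionEvaluation(bin_majority=bin_majority, bin_accuracy=bin_accuracy,
                               source_recall=source_recall, overall_accuracy=overall)


def evaluate_labels(assignment: dict, truth: dict, lengths: dict) -> float:
    """Overall nucleotide accuracy of an arbitrary contig -> label assignment.

    Labels are matched to sources by majority nucleotides (as for bins); the
    return value is the percentage of nucleotides in correctly labelled
    contigs over all assigned nucleotides.
    """
    by_label: dict = {}
    for cid, label in assignment.items():
        src = truth[cid]
        d = by_label.setdefault(label, {})
        d[src] = d.get(src, 0) + lengths[cid]
    correct = 0
    total = 0
    for label, by_source in by_label.items():
        major = max(by_source, key=lambda s: (by_source[s], s))
        correct += by_source[major]
        total += sum(by_source.values())
    return correct / total * 100.0 if total else 0.0
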
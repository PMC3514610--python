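"""Taxonomic profiling of contigs and bins from alignment hits.

Contigs are fragmented into 500 bp pieces, compared against a reference
database with an external aligner, and the tabular hits are filtered and
tallied into five-rank (phylum..genus) profiles.  The aligner itself is not a
dependency: this module consumes standard 12-column tabular output.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus")

#: Hit retention cutoffs: alignment length strictly greater than 200 bp and
#: nucleotide identity of at least 25% (permissive, but applied as printed).
MIN_ALIGN_LENGTH = 200
MIN_PCT_IDENTITY = 25.0


@dataclass(frozen=True)
class Fragment:
    id: str          # "<contig id>:<offset>"
    contig_id: str
    offset: int
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentHit:
    fragment_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.align_length <= 0:
            raise ValueError("align_length must be > 0")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be within [0, 100]")


def fragment_contig(contig, window: int = 500, min_keep: int = 200) -> list:
    """Cut a contig into non-overlapping ``window``-sized pieces from position 0.

    A terminal remainder of at least ``min_keep`` bases is kept as a final
    short fragment; shorter remainders are dropped.  A contig shorter than the
    window but at least ``min_keep`` long yields a single fragment.
    """
    fragments = []
    seq = contig.seq
    pos = 0
    while pos + window <= len(seq):
        fragments.append(Fragment(id=f"{contig.id}:{pos}", contig_id=contig.id,
                                  offset=pos, seq=seq[pos:pos + window]))
        pos += window
    rest = len(seq) - pos
    if rest >= min_keep:
        fragments.append(Fragment(id=f"{contig.id}:{pos}", contig_id=contig.id,
                                  offset=pos, seq=seq[pos:]))
    return fragments


def read_hits(path) -> list:
    """Read BLAST tabular output (outfmt 6, 12 columns) into AlignmentHit rows."""
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, header=None, comment="#")
    return [AlignmentHit(fragment_id=str(r.qseqid), subject_id=str(r.sseqid),
                         pct_identity=float(r.pident), align_length=int(r.length),
                         evalue=float(r.evalue), bitscore=float(r.bitscore))
            for r in df.itertuples()]


def read_lineage(path) -> dict:
    """Lineage TSV (subject_id, phylum..genus) -> dict of five-rank tuples."""
    df = pd.read_csv(path, sep="\t")
    expected = ("subject_id",) + RANKS
    if tuple(str(c).lower() for c in df.columns[:6]) != expected:
        df = pd.read_csv(path, sep="\t", header=None, names=expected)
    return {str(row[0]): tuple(str(x) for x in row[1:6])
            for row in df.itertuples(index=False, name=None)}


def filter_hits(hits) -> list:
    """Apply the length/identity cutoffs, then keep the best hit per fragment.

    Best means highest bitscore, ties broken by lowest e-value then subject id.
    Idempotent.
    """
    passing = [h for h in hits
               if h.align_length > MIN_ALIGN_LENGTH and h.pct_identity >= MIN_PCT_IDENTITY]
    best: dict = {}
    for h in passing:
        cur = best.get(h.fragment_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (-cur.bitscore, cur.evalue, cur.subject_id):
            best[h.fragment_id] = h
    return [best[k] for k in sorted(best)]


@dataclass
class TaxonomicProfile:
    """Per-rank tallies of fragment-best hits.

    ``tallies[rank][taxon]`` is the list of e-values of hits supporting that
    taxon; the majority view (taxon, count, total, median e-value) is derived.
    """

    tallies: dict = field(default_factory=lambda: {rank: {} for rank in RANKS})

    def add_hit(self, lineage_entry: tuple, evalue: float) -> None:
        for rank, taxon in zip(RANKS, lineage_entry):
            self.tallies[rank].setdefault(taxon, []).append(evalue)

    def majority(self, rank: str):
        """(taxon, count, total, median e-value) at a rank, or None if empty."""
        tally = self.tallies[rank]
        if not tally:
            return None
        taxon = max(tally, key=lambda t: (len(tally[t]), t))
        evalues = tally[taxon]
        total = sum(len(v) for v in tally.values())
        return taxon, len(evalues), total, statistics.median(evalues)

    @property
    def empty(self) -> bool:
        return all(not t for t in self.tallies.values())


def contig_profile(hits, lineage: dict) -> TaxonomicProfile:
    """Profile one contig from the retained best hits of its fragments."""
    profile = TaxonomicProfile()
    for h in hits:
        entry = lineage.get(h.subject_id)
        if entry is None:
            log.warning("subject %s missing from lineage table; hit skipped", h.subject_id)
            continue
        profile.add_hit(entry, h.evalue)
    return profile


def bin_profile(contig_profiles) -> TaxonomicProfile:
    """Bin-level profile: per rank, member tallies are summed before the
    majority taxon is taken, so the median e-value pools the majority taxon's
    hits across all members."""
    out = TaxonomicProfile()
    for prof in contig_profiles:
        for rank in RANKS:
            for taxon, evalues in prof.tallies[rank].items():
                out.tallies[rank].setdefault(taxon, []).extend(evalues)
    return out


def profile_contigs(contigs, hits, lineage: dict) -> dict:
    """Profiles for a contig collection from a pooled hit table.

    Fragment ids are expected to encode the contig id as ``<contig>:<offset>``.
    Returns ``{contig_id: TaxonomicProfile}`` (empty profiles included).
    """
    retained = filter_hits(hits)
    by_contig: dict = {c.id: [] for c in contigs}
    for h in retained:
        cid = h.fragment_id.rsplit(":", 1)[0]
        if cid in by_contig:
            by_contig[cid].append(h)
    return {cid: contig_profile(hs, lineage) for cid, hs in by_contig.items()}


def crossvalidate(query_contigs, reference_bins: dict, hits,
                  min_identity: float = 98.0) -> dict:
    """Nucleotides of query contigs recovered to each reference bin.

    ``reference_bins`` maps bin id -> set of reference sequence ids.  For each
    query contig the best hit with identity >= ``min_identity`` (highest
    bitscore, ties by e-value then subject) decides the bin; the contig's full
    length is credited to it.  Queries with no qualifying hit are counted under
    ``None``.
    """
    subject_bin = {}
    for bin_id, members in reference_bins.items():
        for sid in members:
            subject_bin[sid] = bin_id
    best: dict = {}
    for h in hits:
        if h.pct_identity < min_identity:
            continue
        cur = best.get(h.fragment_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (-cur.bitscore, cur.evalue, cur.subject_id):
            best[h.fragment_id] = h
    recovered = {bin_id: 0 for bin_id in reference_bins}
    recovered[None] = 0
    for contig in query_contigs:
        h = best.get(contig.id)
        bin_id = subject_bin.get(h.subject_id) if h is not None else None
        recovered[bin_id] = recovered.get(bin_id, 0) + contig.length
    return recovered
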
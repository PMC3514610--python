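"""Synthetic genomes, communities, alignment-hit fixtures and lineages.

Genomes are sampled from randomly parameterized order-k Markov chains whose
stationary base composition is steered to a GC target.  Markov (rather than
i.i.d.) generation gives each genome a distinctive tetranucleotide signature,
the property the binning method exploits in real genomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import ContigRecord
from .taxprofile import fragment_contig

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

try:
    from numba import njit

    @njit(cache=False)
    def _sample_chain(cum, u, ctx0, mask):  # pragma: no cover - jitted
        n = u.shape[0]
        out = np.empty(n, dtype=np.uint8)
        ctx = ctx0
        for i in range(n):
            r = u[i]
            row = cum[ctx]
            if r < row[0]:
                b = 0
            elif r < row[1]:
                b = 1
            elif r < row[2]:
                b = 2
            else:
                b = 3
            out[i] = b
            ctx = ((ctx << 2) | b) & mask
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in CI image
    _HAVE_NUMBA = False

    def _sample_chain(cum, u, ctx0, mask):
        n = u.shape[0]
        out = np.empty(n, dtype=np.uint8)
        ctx = ctx0
        for i in range(n):
            r = u[i]
            row = cum[ctx]
            b = 0 if r < row[0] else 1 if r < row[1] else 2 if r < row[2] else 3
            out[i] = b
            ctx = ((ctx << 2) | b) & mask
        return out


@dataclass
class SyntheticGenome:
    id: str
    seq: str
    gc_target: float
    order: int
    seed: int

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return (self.seq.count("G") + self.seq.count("C")) / len(self.seq)


@dataclass
class SyntheticCommunity:
    genomes: list
    abundances: np.ndarray
    contigs: list                       # ContigRecord with truth_label set
    truth: dict = field(default_factory=dict)  # contig id -> genome id
    coverages: dict = field(default_factory=dict)  # genome id -> coverage


def _stationary_base_composition(rows: np.ndarray, n_ctx: int) -> np.ndarray:
    """Base marginal of the stationary distribution of the context chain."""
    pi = np.full(n_ctx, 1.0 / n_ctx)
    targets = (np.arange(n_ctx)[:, None] * 4 + np.arange(4)[None, :]) % n_ctx
    for _ in range(200):
        nxt = np.zeros(n_ctx)
        np.add.at(nxt, targets, pi[:, None] * rows)
        if np.abs(nxt - pi).max() < 1e-12:
            pi = nxt
            break
        pi = nxt
    return (pi[:, None] * rows).sum(axis=0)


def make_genome(length: int, gc: float = 0.5, order: int = 3, seed: int = 0,
                concentration: float = 2.0, genome_id: str | None = None) -> SyntheticGenome:
    """Generate one synthetic genome from a random order-``order`` Markov chain.

    Transition rows are Dirichlet-perturbed around the target base composition
    and then iteratively re-weighted so the stationary GC matches ``gc``.
    Deterministic for a fixed seed.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError(f"GC target must be inside (0, 1), got {gc}")
    if length < 10_000:
        raise ValueError(f"genome length must be >= 10 kb, got {length}")
    rng = np.random.default_rng(seed)
    n_ctx = 4 ** order
    p_target = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    rows = rng.dirichlet(concentration * 4 * p_target, size=n_ctx)
    rows = np.maximum(rows, 1e-4)
    rows /= rows.sum(axis=1, keepdims=True)

    w = np.ones(4)
    for _ in range(40):
        adj = rows * w
        adj /= adj.sum(axis=1, keepdims=True)
        q = _stationary_base_composition(adj, n_ctx)
        if np.abs(q - p_target).max() < 1e-4:
            break
        w *= (p_target / np.maximum(q, 1e-9)) ** 0.7
    rows = rows * w
    rows /= rows.sum(axis=1, keepdims=True)

    cum = np.cumsum(rows, axis=1)
    q0 = _stationary_base_composition(rows, n_ctx)
    start = rng.choice(4, size=order, p=q0 / q0.sum())
    ctx = 0
    for b in start:
        ctx = (ctx * 4 + int(b)) % n_ctx
    u = rng.random(length)
    codes = _sample_chain(cum, u, ctx, n_ctx - 1)
    seq = _BASES[codes].tobytes().decode("ascii")
    return SyntheticGenome(id=genome_id or f"g{seed}", seq=seq, gc_target=gc,
                           order=order, seed=seed)


def make_repeat_library(n_elements: int = 20, element_length: int = 2000,
                        gc: float = 0.5, seed: int = 777) -> list:
    """A library of repeat elements cut from one shared Markov 'host' sequence.

    Stands in for conserved mobile elements (transposons, rRNA operons) that
    real genomes share across taxa.  Inserting these into synthetic genomes
    makes short-training-fragment classification realistically hard: a model
    trained on a small window overweights whichever repeats it happened to see.
    """
    rng = np.random.default_rng(seed)
    host = make_genome(max(100_000, n_elements * element_length * 3), gc=gc,
                       seed=int(rng.integers(0, 2 ** 31)), concentration=2.0)
    starts = rng.integers(0, host.length - element_length, n_elements)
    return [host.seq[s:s + element_length] for s in starts]


def insert_repeats(seq: str, library, fraction: float, seed: int = 0) -> str:
    """Scatter library elements through a sequence at ~``fraction`` of its length.

    Elements are inserted (not substituted) at sorted random positions, so the
    result is longer than the input by roughly ``fraction * len(seq)``.
    """
    if fraction <= 0 or not library:
        return seq
    rng = np.random.default_rng(seed)
    mean_len = int(np.mean([len(r) for r in library]))
    n_rep = max(1, int(len(seq) * fraction / mean_len))
    starts = np.sort(rng.integers(0, len(seq) - 1, n_rep))
    out = []
    prev = 0
    for s in starts:
        out.append(seq[prev:s])
        out.append(library[int(rng.integers(0, len(library)))])
        prev = int(s)
    out.append(seq[prev:])
    return "".join(out)


def _draw_contig_lengths(rng, n: int, length_range=None,
                         length_dist: str = "loguniform") -> np.ndarray:
    """Log-normal lengths clipped to [0.5, 100] kb when no range is given;
    otherwise log-uniform (default) or uniform within the range."""
    if length_range is not None:
        lo, hi = length_range
        if length_dist == "uniform":
            return rng.integers(lo, hi + 1, size=n).astype(np.int64)
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(np.int64)
    lengths = rng.lognormal(mean=math.log(5000), sigma=1.0, size=n)
    return np.clip(lengths, 500, 100_000).astype(np.int64)


def make_community(n_genomes: int = 3, genome_length: int = 1_000_000,
                   n_contigs_per_genome: int = 100, contig_length_range=None,
                   length_dist: str = "loguniform", coverages=None,
                   abundances=None, gc_range=(0.35, 0.65),
                   order: int = 3, seed: int = 0) -> SyntheticCommunity:
    """Generate a community of synthetic genomes plus a contig set with truth.

    Contig headers carry the genome's coverage in the velvet-style
    ``..._cov_<x>`` dialect so they round-trip through header parsing.  When
    ``abundances`` are given, contig counts and totals are scaled so per-genome
    nucleotide totals track the abundance ratios.
    """
    master = np.random.default_rng(seed)
    gcs = np.linspace(gc_range[0], gc_range[1], n_genomes) if n_genomes > 1 \
        else np.array([(gc_range[0] + gc_range[1]) / 2])
    genomes = []
    for i in range(n_genomes):
        gseed = int(master.integers(0, 2 ** 31))
        genomes.append(make_genome(genome_length, gc=float(gcs[i]), order=order,
                                   seed=gseed, genome_id=f"g{i + 1}"))
    if abundances is None:
        abundances = np.full(n_genomes, 1.0 / n_genomes)
    else:
        abundances = np.asarray(abundances, dtype=np.float64)
        abundances = abundances / abundances.sum()
    if coverages is None:
        coverages = {g.id: float(master.uniform(5, 50)) for g in genomes}
    elif not isinstance(coverages, dict):
        coverages = {g.id: float(c) for g, c in zip(genomes, coverages)}

    n_total = n_contigs_per_genome * n_genomes
    equal = np.allclose(abundances, abundances[0])
    lo, hi = (500, 100_000) if contig_length_range is None else contig_length_range
    per_genome_lengths = []
    for i in range(n_genomes):
        n_i = n_contigs_per_genome if equal else max(1, int(round(n_total * abundances[i])))
        per_genome_lengths.append(
            _draw_contig_lengths(master, n_i, contig_length_range, length_dist))
    if not equal:
        # rescale draws so realized per-genome totals track the abundance ratios
        grand = sum(lengths.sum() for lengths in per_genome_lengths)
        per_genome_lengths = [
            np.clip((lengths * (grand * a / lengths.sum())).astype(np.int64), lo, hi)
            for lengths, a in zip(per_genome_lengths, abundances)]
    contigs: list[ContigRecord] = []
    truth: dict = {}
    for i, g in enumerate(genomes):
        lengths = per_genome_lengths[i]
        cov = coverages[g.id]
        for k, clen in enumerate(lengths):
            clen = int(min(clen, g.length))
            start = int(master.integers(0, g.length - clen + 1))
            cid = f"{g.id}_c{k:04d}_cov_{cov:.4f}"
            rec = ContigRecord(id=cid, header=cid, seq=g.seq[start:start + clen],
                               coverage=cov, truth_label=g.id)
            contigs.append(rec)
            truth[cid] = g.id
    return SyntheticCommunity(genomes=genomes, abundances=abundances, contigs=contigs,
                              truth=truth, coverages=coverages)


RANKS = ("phylum", "class", "order", "family", "genus")


def default_lineage(community: SyntheticCommunity) -> dict:
    """One distinct five-rank lineage per genome; subject ids are ``ref_<gid>``."""
    lineage = {}
    for i, g in enumerate(community.genomes):
        lineage[f"ref_{g.id}"] = tuple(f"{rank}_{i + 1}" for rank in RANKS)
    return lineage


def make_hits(community: SyntheticCommunity, lineage_assignment: dict | None = None,
              noise: float = 0.0, seed: int = 0, window: int = 500, min_keep: int = 200):
    """Alignment-hit fixture: 12-column rows plus the matching lineage table.

    Every contig fragment gets one correct-subject hit; with probability
    ``noise`` an off-target hit with a strictly higher bitscore is added, so at
    noise=1 every fragment's best hit is off-target.
    Returns ``(rows, lineage)`` where rows are outfmt-6 style tuples.
    """
    rng = np.random.default_rng(seed)
    lineage = lineage_assignment or default_lineage(community)
    subjects = sorted(lineage)
    rows = []
    for rec in community.contigs:
        own = f"ref_{rec.truth_label}"
        for frag in fragment_contig(rec, window=window, min_keep=min_keep):
            flen = frag.length
            ident = float(rng.uniform(85, 99))
            evalue = float(10.0 ** rng.uniform(-60, -20))
            bitscore = round(flen * 1.8 + rng.uniform(0, 20), 1)
            rows.append((frag.id, own, round(ident, 2), flen, 0, 0, 1, flen,
                         1, flen, evalue, bitscore))
            others = [s for s in subjects if s != own]
            if others and rng.random() < noise:
                off = others[int(rng.integers(0, len(others)))]
                rows.append((frag.id, off, round(float(rng.uniform(85, 99)), 2), flen,
                             0, 0, 1, flen, 1, flen,
                             float(10.0 ** rng.uniform(-60, -20)), bitscore + 10.0))
    return rows, lineage


def write_hits(rows, path) -> None:
    """Write hit rows as BLAST tabular (outfmt 6), no header."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_lineage(lineage: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id\t" + "\t".join(RANKS) + "\n")
        for subject in sorted(lineage):
            fh.write(subject + "\t" + "\t".join(lineage[subject]) + "\n")


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tsource_id\n")
        for cid in truth:
            fh.write(f"{cid}\t{truth[cid]}\n")


def read_truth(path) -> dict:
    truth = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            cid, src = line.rstrip("\n").split("\t")
            truth[cid] = src
    return truth
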
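"""Interpolated Markov models for the second (rebinning) stage.

One model is trained per selected seed bin, on both strands of its member
sequences; every contig is then scored against every model and assigned to the
highest-scoring one.  The model blends maximum-likelihood conditional
probabilities across context lengths 0..K, weighting each order by how often
its context was seen during training: lambda_k = min(1, count_k / C), applied
recursively as P_k = lambda_k * MLE_k + (1 - lambda_k) * P_{k-1}.  No
background ("negative") model is subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tetra import encode

log = logging.getLogger(__name__)

DEFAULT_MAX_ORDER = 8
DEFAULT_INTERPOLATION_THRESHOLD = 400
DEFAULT_PSEUDOCOUNT = 1.0

_P_FLOOR = 1e-12  # keeps log-likelihoods finite for never-seen transitions
_COMP = np.array([3, 2, 1, 0, -1], dtype=np.int8)  # code complement; -1 stays -1


@dataclass
class ImmModel:
    max_order: int
    interpolation_threshold: int
    pseudocount: float
    counts: list                    # counts[k]: (4**k, 4) int64
    training_length: int = 0        # nucleotides seen (both strands)
    label: str = ""

    def conditional(self, k: int) -> np.ndarray:
        """Maximum-likelihood conditional table at order k (rows sum to 1).

        Rows for contexts never seen in training fall back to uniform; the
        pseudocount only enters order-0 scoring, not this view.
        """
        c = self.counts[k].astype(np.float64)
        rowsum = c.sum(axis=1, keepdims=True)
        out = np.divide(c, rowsum, out=np.full_like(c, 0.25), where=rowsum > 0)
        return out


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def _context_arrays(codes: np.ndarray, max_order: int):
    """Per-order context codes and validity masks for every position.

    ``ctx[k][i]`` encodes codes[i-k:i]; ``ok[k][i]`` is False when the context
    extends past the start or crosses a non-ACGT character.
    """
    n = codes.shape[0]
    valid = codes >= 0
    ctxs = [np.zeros(n, dtype=np.int64)]
    oks = [np.ones(n, dtype=bool)]
    for k in range(1, max_order + 1):
        prev_ctx, prev_ok = ctxs[k - 1], oks[k - 1]
        ctx = np.zeros(n, dtype=np.int64)
        ok = np.zeros(n, dtype=bool)
        if n > k:
            ctx[k:] = codes[:-k].astype(np.int64) * 4 ** (k - 1) + prev_ctx[k:]
            ok[k:] = prev_ok[k:] & valid[:-k]
        ctxs.append(ctx)
        oks.append(ok)
    return ctxs, oks, valid


def train(sequences, max_order: int = DEFAULT_MAX_ORDER,
          interpolation_threshold: int = DEFAULT_INTERPOLATION_THRESHOLD,
          pseudocount: float = DEFAULT_PSEUDOCOUNT, label: str = "") -> ImmModel:
    """Train an interpolated Markov model on a collection of sequences.

    Counts accumulate over both the sequence and its reverse complement,
    mirroring the strand symmetry of the tetranucleotide stage.  Non-ACGT
    positions break contexts.
    """
    seqs = [s.seq if hasattr(s, "seq") else s for s in sequences]
    seqs = [s for s in seqs if s]
    if not seqs:
        raise ValueError("cannot train an IMM on an empty sequence set")
    counts = [np.zeros((4 ** k, 4), dtype=np.int64) for k in range(max_order + 1)]
    training_length = 0
    for seq in seqs:
        codes = encode(seq)
        for strand in (codes, _revcomp_codes(codes)):
            training_length += strand.shape[0]
            ctxs, oks, valid = _context_arrays(strand, max_order)
            base = strand.astype(np.int64)
            for k in range(max_order + 1):
                use = oks[k] & valid
                if not use.any():
                    continue
                flat = ctxs[k][use] * 4 + base[use]
                counts[k] += np.bincount(flat, minlength=4 ** k * 4).reshape(-1, 4)
    return ImmModel(max_order=max_order, interpolation_threshold=interpolation_threshold,
                    pseudocount=pseudocount, counts=counts,
                    training_length=training_length, label=label)


def score(model: ImmModel, seq: str) -> float:
    """Log-likelihood of a sequence under the model.

    Per position, probabilities interpolate from order K down to the
    pseudocount-smoothed order-0 composition; non-ACGT positions contribute 0
    and reset the context.
    """
    codes = encode(seq.seq if hasattr(seq, "seq") else seq)
    n = codes.shape[0]
    if n == 0:
        return 0.0
    ctxs, oks, valid = _context_arrays(codes, model.max_order)
    base = np.where(valid, codes, 0).astype(np.int64)

    c0 = model.counts[0][0].astype(np.float64) + model.pseudocount
    p = (c0 / c0.sum())[base]
    C = float(model.interpolation_threshold)
    for k in range(1, model.max_order + 1):
        tab = model.counts[k]
        ctx = ctxs[k]
        rows = tab[ctx]                       # (n, 4)
        rowsum = rows.sum(axis=1).astype(np.float64)
        lam = np.minimum(1.0, rowsum / C)
        lam[~oks[k]] = 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            mle = rows[np.arange(n), base] / rowsum
        mle[rowsum == 0] = 0.0
        p = lam * mle + (1.0 - lam) * p
    p = np.maximum(p, _P_FLOOR)
    return float(np.log(p[valid]).sum())


def assign(models, contigs) -> dict:
    """Assign every contig to the model with the highest score.

    Returns contig id -> (label, score).  Ties go to the model trained on more
    nucleotides, then the lexicographically smallest label; the result does not
    depend on model ordering.
    """
    if not models:
        raise ValueError("need at least one model")
    ranked = sorted(models, key=lambda m: (-m.training_length, m.label))
    out = {}
    for contig in contigs:
        best = None
        best_score = -np.inf
        for m in ranked:
            s = score(m, contig)
            if s > best_score:
                best, best_score = m, s
        out[contig.id if hasattr(contig, "id") else id(contig)] = (best.label, best_score)
    return out


def select_seed_bins(results, min_bin_length: int, max_coverage_cv: float,
                     min_majority_fraction: float) -> list:
    """Rank bins as IMM seed candidates by length, coverage homogeneity and
    taxonomic consistency.

    ``results`` is an iterable of BinningResult.  Returns one diagnostic dict
    per bin with a ``passed`` flag; gates only apply where the underlying data
    (coverage, profile) is available.  This is a report for the user to accept
    or override — models are never trained from it implicitly.
    """
    report = []
    for res in results:
        for b in res.bins:
            covs = [c for c in b.coverage_values if c is not None]
            if covs:
                mean = float(np.mean(covs))
                cv = float(np.std(covs) / mean) if mean > 0 else 0.0
            else:
                cv = None
            majority_fraction = None
            if b.profile is not None and not b.profile.empty:
                maj = b.profile.majority("genus")
                if maj is not None:
                    _, count, total, _ = maj
                    majority_fraction = count / total if total else None
            passed = b.total_length >= min_bin_length
            if cv is not None:
                passed = passed and cv <= max_coverage_cv
            if majority_fraction is not None:
                passed = passed and majority_fraction >= min_majority_fraction
            report.append({
                "confidence": res.confidence, "bin_id": b.id,
                "total_length": b.total_length, "n_contigs": len(b.members),
                "coverage_cv": cv, "majority_fraction": majority_fraction,
                "passed": passed,
            })
    report.sort(key=lambda r: (not r["passed"], -r["total_length"]))
    return report


# -- model serialization (versioned text format) ------------------------------

def save_model(model: ImmModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("#tetrabin-imm\t1\n")
        fh.write(f"#label\t{model.label}\n")
        fh.write(f"#max_order\t{model.max_order}\n")
        fh.write(f"#interpolation_threshold\t{model.interpolation_threshold}\n")
        fh.write("#pseudocount\t%.17g\n" % model.pseudocount)
        fh.write(f"#training_length\t{model.training_length}\n")
        for k in range(model.max_order + 1):
            tab = model.counts[k]
            nz = np.flatnonzero(tab.sum(axis=1))
            for ctx in nz:
                fh.write(f"{k}\t{ctx}\t" + "\t".join(str(int(x)) for x in tab[ctx]) + "\n")


def load_model(path) -> ImmModel:
    meta = {}
    rows = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#tetrabin-imm"):
            raise ValueError(f"{path}: not an IMM model file")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, value = line[1:].split("\t", 1)
                meta[key] = value
            elif line:
                rows.append(line.split("\t"))
    max_order = int(meta["max_order"])
    counts = [np.zeros((4 ** k, 4), dtype=np.int64) for k in range(max_order + 1)]
    for parts in rows:
        k, ctx = int(parts[0]), int(parts[1])
        counts[k][ctx] = [int(x) for x in parts[2:6]]
    return ImmModel(max_order=max_order,
                    interpolation_threshold=int(meta["interpolation_threshold"]),
                    pseudocount=float(meta["pseudocount"]), counts=counts,
                    training_length=int(meta["training_length"]),
                    label=meta.get("label", ""))
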
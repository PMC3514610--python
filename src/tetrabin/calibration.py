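"""Empirical calibration of the tetranucleotide Gaussian membership model.

Two lookup tables are built by sampling artificial contigs from reference
genomes:

* ``SigmaTable`` — the dispersion of a class's frequency in fragments of length
  *l* drawn from a genome whose mean frequency for that class is *m*.  No
  satisfactory closed form exists for this relationship, so it is tabulated and
  interpolated (linear in *m*, linear in log *l*).
* ``ThresholdTable`` — log-probability cutoffs per fragment length calibrated so
  that 90 / 95 / 98 % of same-genome fragments are accepted ("high", "medium"
  and "low" confidence respectively).

The membership score of a fragment with vector *v* against a source mean vector
*m* is the sum over the 136 classes of the log Gaussian density with the
table-derived per-class standard deviation.  All arithmetic is in log space; a
naive product of 136 densities underflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tetra import (N_CLASSES, FrequencyVector, encode, frequency_from_classes,
                    window_classes)

log = logging.getLogger(__name__)

#: Fragment lengths (bases) sampled during calibration: 0.3–100 kb.
LENGTH_GRID = tuple(
    int(x * 1000) for x in
    (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4, 1.5,
     1.75, 2, 2.25, 2.5, 2.75, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 18, 20,
     25, 30, 40, 50, 60, 70, 80, 100)
)

CONFIDENCES = (90, 95, 98)

MEAN_BIN_WIDTH = 0.05
MEAN_MAX = 4.0
SIGMA_FLOOR = 1e-3

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class CalibrationError(RuntimeError):
    pass


@dataclass
class SigmaTable:
    """Dispersion lookup: sigma[mean-frequency bin, fragment length]."""

    lengths: np.ndarray          # (n_len,) ordered fragment lengths
    mean_centers: np.ndarray     # (n_mean,) bin centers of the mean-frequency axis
    sigma: np.ndarray            # (n_mean, n_len)
    sample_counts: np.ndarray    # (n_mean, n_len) contributing observations

    def lookup_vec(self, m: np.ndarray, length: float) -> np.ndarray:
        """Interpolated sigma for an array of mean frequencies at one length.

        Linear in m, linear in log(length); both axes clamped to the grid; the
        result is floored at SIGMA_FLOOR.
        """
        logl = np.log(np.clip(length, self.lengths[0], self.lengths[-1]))
        logg = np.log(self.lengths)
        j1 = int(np.searchsorted(logg, logl))
        if j1 <= 0:
            col = self.sigma[:, 0]
        elif j1 >= len(logg):
            col = self.sigma[:, -1]
        else:
            j0 = j1 - 1
            w = (logl - logg[j0]) / (logg[j1] - logg[j0])
            col = self.sigma[:, j0] * (1.0 - w) + self.sigma[:, j1] * w
        mc = np.clip(np.asarray(m, dtype=np.float64), self.mean_centers[0], self.mean_centers[-1])
        out = np.interp(mc, self.mean_centers, col)
        return np.maximum(out, SIGMA_FLOOR)

    def lookup(self, m: float, length: float) -> float:
        return float(self.lookup_vec(np.array([m]), length)[0])


@dataclass
class ThresholdTable:
    """Log-probability acceptance thresholds per confidence level and length."""

    lengths: np.ndarray                    # (n_len,)
    log_thresholds: np.ndarray             # (len(CONFIDENCES), n_len), rows follow CONFIDENCES

    def threshold(self, confidence: int, length: float) -> float:
        """Cutoff for one confidence level, linear in log(length), clamped."""
        if confidence not in CONFIDENCES:
            raise ValueError(f"confidence must be one of {CONFIDENCES}, got {confidence}")
        row = self.log_thresholds[CONFIDENCES.index(confidence)]
        logl = np.log(np.clip(length, self.lengths[0], self.lengths[-1]))
        return float(np.interp(logl, np.log(self.lengths), row))


@dataclass
class CalibrationTables:
    sigma_table: SigmaTable
    threshold_table: ThresholdTable
    provenance: dict = field(default_factory=dict)

    def threshold(self, confidence: int, length: float) -> float:
        return self.threshold_table.threshold(confidence, length)

    # -- serialization: versioned plain-text format ---------------------------

    def save(self, path) -> None:
        st, tt = self.sigma_table, self.threshold_table
        with open(path, "w") as fh:
            fh.write("#tetrabin-calibration\t1\n")
            for key in sorted(self.provenance):
                fh.write(f"#prov\t{key}\t{self.provenance[key]}\n")
            fh.write("#lengths\t" + "\t".join(str(int(x)) for x in st.lengths) + "\n")
            fh.write("#mean_centers\t" + "\t".join("%.17g" % x for x in st.mean_centers) + "\n")
            fh.write("#sigma\n")
            for row in st.sigma:
                fh.write("\t".join("%.17g" % x for x in row) + "\n")
            fh.write("#counts\n")
            for row in st.sample_counts:
                fh.write("\t".join(str(int(x)) for x in row) + "\n")
            fh.write("#thresholds\n")
            for conf, row in zip(CONFIDENCES, tt.log_thresholds):
                fh.write(str(conf) + "\t" + "\t".join("%.17g" % x for x in row) + "\n")

    @classmethod
    def load(cls, path) -> "CalibrationTables":
        provenance: dict = {}
        lengths = mean_centers = None
        sigma_rows: list = []
        count_rows: list = []
        thr_rows: dict = {}
        section = None
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#tetrabin-calibration"):
                raise CalibrationError(f"{path}: not a calibration table file")
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#prov\t"):
                    _, key, value = line.split("\t", 2)
                    provenance[key] = value
                elif line.startswith("#lengths\t"):
                    lengths = np.array([int(x) for x in line.split("\t")[1:]], dtype=np.float64)
                elif line.startswith("#mean_centers\t"):
                    mean_centers = np.array([float(x) for x in line.split("\t")[1:]])
                elif line == "#sigma":
                    section = "sigma"
                elif line == "#counts":
                    section = "counts"
                elif line == "#thresholds":
                    section = "thresholds"
                elif section == "sigma":
                    sigma_rows.append([float(x) for x in line.split("\t")])
                elif section == "counts":
                    count_rows.append([int(x) for x in line.split("\t")])
                elif section == "thresholds":
                    parts = line.split("\t")
                    thr_rows[int(parts[0])] = [float(x) for x in parts[1:]]
        if lengths is None or mean_centers is None or not sigma_rows:
            raise CalibrationError(f"{path}: incomplete calibration table")
        st = SigmaTable(lengths=lengths, mean_centers=mean_centers,
                        sigma=np.array(sigma_rows),
                        sample_counts=np.array(count_rows, dtype=np.int64))
        tt = ThresholdTable(lengths=lengths,
                            log_thresholds=np.array([thr_rows[c] for c in CONFIDENCES]))
        return cls(sigma_table=st, threshold_table=tt, provenance=provenance)


# -- fragment sampling --------------------------------------------------------

def sample_fragments(genome: str, lengths, n_per_length: int, seed: int) -> dict:
    """Sample ``n_per_length`` substrings at uniform random starts per length.

    Lengths exceeding the genome are skipped with a warning.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out: dict = {}
    glen = len(genome)
    for length in lengths:
        if glen <= length:
            log.warning("genome of %d bp shorter than requested fragment length %d; skipped",
                        glen, length)
            continue
        starts = rng.integers(0, glen - length + 1, size=n_per_length)
        out[length] = [genome[s:s + length] for s in starts]
    return out


def _sample_starts(rng, glen: int, length: int, n: int) -> np.ndarray:
    return rng.integers(0, glen - length + 1, size=n)


def _fragment_matrix(classes: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    """Frequency vectors of fragments [s, s+length) from a precomputed
    window-class array; rows with no valid window are left as zeros."""
    nwin = length - 3
    out = np.empty((len(starts), N_CLASSES))
    for i, s in enumerate(starts):
        sl = classes[s:s + nwin]
        valid = sl[sl >= 0] if (sl < 0).any() else sl
        counts = np.bincount(valid, minlength=N_CLASSES).astype(np.float64)
        matched = counts.sum()
        out[i] = counts / matched * N_CLASSES if matched > 0 else 0.0
    return out


def _coerce_genomes(genomes) -> list:
    """Accept plain strings, (id, seq) pairs, or objects with .id/.seq."""
    out = []
    for i, g in enumerate(genomes):
        if isinstance(g, str):
            out.append((f"genome{i}", g))
        elif isinstance(g, tuple):
            out.append(g)
        else:
            out.append((getattr(g, "id", f"genome{i}"), g.seq))
    return out


def build_tables(genomes, lengths=LENGTH_GRID, n_per_length: int = 100,
                 seed: int = 0, mean_bin_width: float = MEAN_BIN_WIDTH,
                 mean_max: float = MEAN_MAX) -> CalibrationTables:
    """Build SigmaTable and ThresholdTable from one fragment-sampling run.

    For each genome the whole-genome mean vector is computed; for each grid
    length, ``n_per_length`` fragments are sampled and the per-class standard
    deviation across the fragment population is recorded against the genome
    mean for that class.  Observations from all genomes and classes are pooled
    into mean-frequency bins and averaged per (bin, length) cell.  Thresholds
    are then the (100−confidence)-th percentile of each fragment's
    log-probability against its own source genome, pooled over genomes.
    """
    genomes = _coerce_genomes(genomes)
    lengths = np.array(sorted(int(x) for x in lengths), dtype=np.int64)
    n_mean = int(round(mean_max / mean_bin_width))
    mean_centers = (np.arange(n_mean) + 0.5) * mean_bin_width

    rng = np.random.default_rng(seed)
    sum_sigma = np.zeros((n_mean, len(lengths)))
    counts = np.zeros((n_mean, len(lengths)), dtype=np.int64)

    usable = []   # (genome_mean_values, [(length_index, F matrix), ...])
    for gid, seq in genomes:
        classes = window_classes(encode(seq))
        gvec = frequency_from_classes(classes)
        if not gvec.defined:
            log.warning("genome %s has no valid tetranucleotide window; excluded", gid)
            continue
        mean_vals = gvec.values
        mbin = np.clip((mean_vals / mean_bin_width).astype(np.int64), 0, n_mean - 1)
        frames = []
        glen = len(seq)
        for j, length in enumerate(lengths):
            if glen <= length:
                log.warning("genome %s (%d bp) shorter than fragment length %d; skipped",
                            gid, glen, length)
                continue
            starts = _sample_starts(rng, glen, int(length), n_per_length)
            F = _fragment_matrix(classes, starts, int(length))
            s_vec = F.std(axis=0, ddof=1)
            np.add.at(sum_sigma[:, j], mbin, s_vec)
            np.add.at(counts[:, j], mbin, 1)
            frames.append((j, F))
        usable.append((mean_vals, frames))

    if len(usable) < 2:
        raise CalibrationError(f"need at least 2 usable genomes, got {len(usable)}")

    sigma = np.zeros_like(sum_sigma)
    populated = counts > 0
    sigma[populated] = sum_sigma[populated] / counts[populated]
    # empty cells inherit the nearest populated cell along the mean axis
    for j in range(len(lengths)):
        col_pop = np.flatnonzero(populated[:, j])
        if col_pop.size == 0:
            raise CalibrationError(f"no observations at fragment length {lengths[j]}")
        col_empty = np.flatnonzero(~populated[:, j])
        if col_empty.size:
            nearest = col_pop[np.argmin(np.abs(col_empty[:, None] - col_pop[None, :]), axis=1)]
            sigma[col_empty, j] = sigma[nearest, j]
    sigma = np.maximum(sigma, SIGMA_FLOOR)

    sigma_table = SigmaTable(lengths=lengths.astype(np.float64), mean_centers=mean_centers,
                             sigma=sigma, sample_counts=counts)

    # pass 2: thresholds from same-genome fragment log-probabilities
    pooled = [[] for _ in lengths]
    for mean_vals, frames in usable:
        for j, F in frames:
            s = sigma_table.lookup_vec(mean_vals, float(lengths[j]))
            const = -(np.log(s) + _LOG_SQRT_2PI).sum()
            logps = const - 0.5 * (((F - mean_vals) / s) ** 2).sum(axis=1)
            pooled[j].append(logps)
    log_thresholds = np.empty((len(CONFIDENCES), len(lengths)))
    for ci, conf in enumerate(CONFIDENCES):
        for j in range(len(lengths)):
            allp = np.concatenate(pooled[j])
            log_thresholds[ci, j] = np.percentile(allp, 100 - conf)
    # the threshold-vs-length relationship is smooth; a local quadratic fit in
    # log(l) suppresses per-length percentile estimation noise
    if len(lengths) >= 7:
        log_thresholds = np.array([
            _smooth_local_quadratic(np.log(lengths.astype(np.float64)), row)
            for row in log_thresholds])
        # smoothing is per-row; re-impose the recall ordering invariant
        for ci in range(1, len(CONFIDENCES)):
            log_thresholds[ci] = np.minimum(log_thresholds[ci], log_thresholds[ci - 1])

    threshold_table = ThresholdTable(lengths=lengths.astype(np.float64),
                                     log_thresholds=log_thresholds)
    provenance = {"genomes": len(usable), "n_per_length": n_per_length, "seed": seed,
                  "n_lengths": len(lengths)}
    return CalibrationTables(sigma_table=sigma_table, threshold_table=threshold_table,
                             provenance=provenance)


def _smooth_local_quadratic(x: np.ndarray, y: np.ndarray, half_window: int = 3) -> np.ndarray:
    """Savitzky-Golay-style smoothing: per point, fit a quadratic over the
    surrounding window (clipped at the edges) and evaluate at the point."""
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        if hi - lo < 4:
            out[i] = y[i]
            continue
        coef = np.polyfit(x[lo:hi] - x[i], y[lo:hi], 2)
        out[i] = coef[-1]
    return out


# -- membership probability ---------------------------------------------------

def log_probability(v: FrequencyVector, m: FrequencyVector, length: float,
                    sigma_table: SigmaTable, abort_below: float | None = None,
                    chunk: int = 17):
    """Log multivariate Gaussian membership score of vector *v* against mean *m*.

    Sum over the 136 classes of the log normal density with per-class sigma
    from the dispersion table at (m_x, length).  With ``abort_below`` set, the
    sum may stop early — but only when the partial sum plus an upper bound on
    all remaining terms (suffix sums of the per-class density maxima
    −log(√(2π)·σ_x)) is already below the cutoff, which makes the accept/reject
    decision identical to the full sum.  Returns ``(value, aborted)``; an
    aborted value is ≤ abort_below.
    """
    if not (v.defined and m.defined):
        raise ValueError("log_probability requires defined frequency vectors")
    s = sigma_table.lookup_vec(m.values, length)
    terms = -0.5 * ((v.values - m.values) / s) ** 2 - np.log(s) - _LOG_SQRT_2PI
    if abort_below is None:
        return float(terms.sum()), False
    # per-class maximum of each log-density term (attained at v_x == m_x)
    maxima = -np.log(s) - _LOG_SQRT_2PI
    suffix = np.concatenate([np.cumsum(maxima[::-1])[::-1], [0.0]])
    partial = 0.0
    n = terms.shape[0]
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        partial += float(terms[start:stop].sum())
        if stop < n:
            bound = partial + float(suffix[stop])
            if bound < abort_below:
                return bound, True
    return partial, False
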
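"""Canonical tetranucleotide classes and normalized 136-dimensional frequency vectors.

Every DNA tetranucleotide is identified with its reverse complement, collapsing
the 256 possible 4-mers into 136 canonical classes (120 two-member pairs plus 16
palindromes).  A sequence is summarised by the per-class window counts over all
4-base sliding windows that contain only A/C/G/T, normalized so the 136 values
sum to 136 (i.e. the vector mean is exactly 1 for any valid sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_CLASSES = 136

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> base code (A=0, C=1, G=2, T=3); anything else (incl. N) -> -1
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CanonicalMap:
    """Mapping of all 256 tetranucleotides onto their 136 canonical classes.

    Attributes
    ----------
    class_of : ndarray of shape (256,)
        Class index for each 4-mer code (lexicographic A<C<G<T encoding).
    palindromic : ndarray of shape (136,) of bool
        True for classes whose single member is its own reverse complement.
    representatives : tuple of str
        Lexicographically smallest member of each class, in class-index order.
    """

    class_of: np.ndarray
    palindromic: np.ndarray
    representatives: tuple

    @property
    def class_count(self) -> int:
        return int(self.class_of.max()) + 1

    def index_of(self, kmer: str) -> int:
        """Class index of a 4-mer given as a string."""
        if len(kmer) != 4:
            raise ValueError(f"expected a tetranucleotide, got {kmer!r}")
        codes = _ENC[np.frombuffer(kmer.encode("ascii"), dtype=np.uint8)]
        if (codes < 0).any():
            raise ValueError(f"non-ACGT tetranucleotide {kmer!r}")
        code = int(codes[0]) * 64 + int(codes[1]) * 16 + int(codes[2]) * 4 + int(codes[3])
        return int(self.class_of[code])


def _decode(code: int) -> str:
    return "".join(_BASES[(code >> (2 * (3 - i))) & 3] for i in range(4))


def build_canonical_map() -> CanonicalMap:
    """Build the deterministic 256 -> 136 canonical class map.

    Classes are indexed in lexicographic order of their smallest member, which
    makes frequency vectors comparable across runs and serializable.
    """
    class_of = np.full(256, -1, dtype=np.int16)
    palindromic = []
    representatives = []
    for code in range(256):  # lexicographic order by construction
        if class_of[code] >= 0:
            continue
        kmer = _decode(code)
        rc = reverse_complement(kmer)
        rc_codes = _ENC[np.frombuffer(rc.encode("ascii"), dtype=np.uint8)]
        rc_code = int(rc_codes[0]) * 64 + int(rc_codes[1]) * 16 + int(rc_codes[2]) * 4 + int(rc_codes[3])
        idx = len(representatives)
        class_of[code] = idx
        class_of[rc_code] = idx
        representatives.append(kmer)
        palindromic.append(rc_code == code)
    return CanonicalMap(
        class_of=class_of,
        palindromic=np.asarray(palindromic, dtype=bool),
        representatives=tuple(representatives),
    )


_DEFAULT_MAP: CanonicalMap | None = None


def canonical_map() -> CanonicalMap:
    """Module-level cached default canonical map."""
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = build_canonical_map()
    return _DEFAULT_MAP


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to base codes; non-ACGT characters become -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def window_classes(codes: np.ndarray, cmap: CanonicalMap | None = None) -> np.ndarray:
    """Canonical class index of every 4-base sliding window.

    Windows containing a non-ACGT character are marked -1.  Returns an array of
    length ``len(codes) - 3`` (empty for shorter inputs).
    """
    if cmap is None:
        cmap = canonical_map()
    n = codes.shape[0]
    if n < 4:
        return np.empty(0, dtype=np.int16)
    c0 = codes[:-3].astype(np.int32)
    c1 = codes[1:-2].astype(np.int32)
    c2 = codes[2:-1].astype(np.int32)
    c3 = codes[3:].astype(np.int32)
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)
    idx = c0 * 64 + c1 * 16 + c2 * 4 + c3
    out = np.where(valid, cmap.class_of[np.where(valid, idx, 0)], -1)
    return out.astype(np.int16)


@dataclass
class FrequencyVector:
    """Normalized canonical tetranucleotide frequencies of one sequence.

    ``values`` holds the 136 per-class frequencies, scaled so that they sum to
    136 when at least one valid window was observed.  ``matched_windows`` is the
    number of 4-base windows free of non-ACGT characters; when it is zero the
    vector is undefined and ``values`` is all zeros.
    """

    values: np.ndarray
    matched_windows: int

    @property
    def defined(self) -> bool:
        return self.matched_windows > 0


def frequency_from_classes(classes: np.ndarray) -> FrequencyVector:
    """Frequency vector from a precomputed window-class array (−1 = invalid)."""
    if classes.size and (classes >= 0).all():
        counts = np.bincount(classes, minlength=N_CLASSES).astype(np.float64)
    else:
        valid = classes[classes >= 0]
        counts = np.bincount(valid, minlength=N_CLASSES).astype(np.float64)
    matched = int(counts.sum())
    if matched == 0:
        return FrequencyVector(values=np.zeros(N_CLASSES), matched_windows=0)
    return FrequencyVector(values=counts / matched * N_CLASSES, matched_windows=matched)


def frequency_vector(seq: str, cmap: CanonicalMap | None = None) -> FrequencyVector:
    """Compute the 136-entry normalized frequency vector of a sequence.

    Windows slide by one base; windows containing non-ACGT characters are
    skipped and excluded from the normalization denominator.
    """
    return frequency_from_classes(window_classes(encode(seq), cmap))


def weighted_mean_vector(vectors, weights) -> FrequencyVector:
    """Weight-averaged frequency vector (weights are typically contig lengths)."""
    vals = np.zeros(N_CLASSES)
    total_w = 0.0
    total_mw = 0
    for v, w in zip(vectors, weights):
        if not v.defined:
            continue
        vals += v.values * w
        total_w += w
        total_mw += v.matched_windows
    if total_w == 0:
        return FrequencyVector(values=np.zeros(N_CLASSES), matched_windows=0)
    return FrequencyVector(values=vals / total_w, matched_windows=total_mw)


def write_vectors(path, ids, vectors) -> None:
    """Debug export: one row per sequence, id + 136 tab-separated frequencies."""
    cmap = canonical_map()
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(cmap.representatives) + "\n")
        for cid, vec in zip(ids, vectors):
            fh.write(cid + "\t" + "\t".join("%.17g" % x for x in vec.values) + "\n")


def read_vectors(path):
    """Read a table written by :func:`write_vectors` -> (ids, vectors)."""
    ids, vectors = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: not a frequency-vector table")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            vals = np.array([float(x) for x in parts[1:]])
            mw = 1 if vals.sum() > 0 else 0
            vectors.append(FrequencyVector(values=vals, matched_windows=mw))
    return ids, vectors
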
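"""FASTA reading/writing and extraction of sequencing coverage from assembler headers."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

# Applied to the lower-cased header; matches velvet-style "cov_22.7" as well as
# "coverage=12" dialects.  The explicit coverage value always wins over numreads.
COVERAGE_PATTERN = re.compile(r"cov[a-z]*?[=_]([\d.]+)")
NUMREADS_PATTERN = re.compile(r"numreads\s*=\s*(\d+)")


class FastaFormatError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


@dataclass
class ContigRecord:
    """One assembled contig.

    ``header`` is the full original header text (without '>'); ``id`` is its
    first whitespace-delimited token.  Sequences are upper-cased on input.
    ``truth_label`` carries the source-genome identifier in simulations.
    """

    id: str
    header: str
    seq: str
    coverage: float | None = None
    truth_label: str | None = None

    def __post_init__(self):
        self.seq = self.seq.upper()
        if self.coverage is not None and self.coverage <= 0:
            raise ValueError(f"contig {self.id}: coverage must be > 0")

    @property
    def length(self) -> int:
        return len(self.seq)


def read_fasta(path) -> list[ContigRecord]:
    """Read a FASTA file into an ordered list of :class:`ContigRecord`.

    Raises :class:`FastaFormatError` for text before the first '>' or an entry
    with an empty sequence, naming the line number.
    """
    records: list[ContigRecord] = []
    header = None
    header_line = 0
    chunks: list[str] = []

    def _flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(f"{path}: entry at line {header_line} has an empty sequence")
        records.append(ContigRecord(id=header.split()[0] if header.split() else header,
                                    header=header, seq=seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if line.startswith(">"):
                _flush()
                header = line[1:]
                header_line = lineno
                chunks = []
            elif line.strip():
                if header is None:
                    raise FastaFormatError(f"{path}: line {lineno}: sequence data before first '>'")
                chunks.append(line.strip())
        _flush()
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write contigs as FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(">" + rec.header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def parse_coverage(header: str, mean_read_length: float | None = None,
                   contig_length: int | None = None) -> float | None:
    """Extract sequencing coverage from an assembler FASTA header.

    The explicit coverage pattern is tried first on the lower-cased header; if
    only a read count is present, coverage is estimated as
    ``numreads * mean_read_length / contig_length``.  Returns None when neither
    pattern applies (or the fallback lacks its inputs, with a logged warning).
    """
    low = header.lower()
    m = COVERAGE_PATTERN.search(low)
    if m:
        try:
            value = float(m.group(1))
        except ValueError:
            value = None
        if value is not None:
            return value
    m = NUMREADS_PATTERN.search(low)
    if m:
        numreads = int(m.group(1))
        if mean_read_length is None or contig_length is None:
            log.warning("header %r carries numreads but no mean read length/contig length "
                        "was supplied; coverage left absent", header)
            return None
        return numreads * mean_read_length / contig_length
    return None


def attach_coverage(records, mean_read_length: float | None = None) -> None:
    """Fill ``coverage`` on each record from its header, in place."""
    for rec in records:
        cov = parse_coverage(rec.header, mean_read_length, rec.length)
        if cov is not None and cov > 0:
            rec.coverage = cov
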
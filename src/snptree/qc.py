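"""Read pre-processing.

Early Illumina single-read runs frequently emitted an uncalled base in the
final cycle; in the kind of 40 bp cDNA data this pipeline targets, well over
half of all reads can end in a single N.  QC therefore does exactly two
things, in order: strip one trailing N, then discard any read that still
contains an N anywhere.  Reads left shorter than a minimum length after
trimming are discarded too (a degenerate read cannot seed k-mers), counted
separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import Read

DEFAULT_MIN_LENGTH = 20


@dataclass
class QcReport:
    input_reads: int = 0
    trailing_n_trimmed: int = 0
    discarded_n_reads: int = 0
    discarded_short_reads: int = 0

    @property
    def surviving_reads(self) -> int:
        return self.input_reads - self.discarded_n_reads - self.discarded_short_reads

    def as_tsv(self) -> str:
        rows = [
            ("input_reads", self.input_reads),
            ("trailing_n_trimmed", self.trailing_n_trimmed),
            ("discarded_n_reads", self.discarded_n_reads),
            ("discarded_short_reads", self.discarded_short_reads),
            ("surviving_reads", self.surviving_reads),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.as_tsv())


def trim_trailing_n(read: Read) -> Read:
    """Remove a single N from the last position, if present.

    Only the final base is ever touched; internal Ns are left for the
    filtering step.  Raises ``ValueError`` on an empty read.
    """
    if not read.sequence:
        raise ValueError(f"empty read {read.read_id!r}")
    if read.sequence[-1] == "N":
        return read.with_sequence(read.sequence[:-1])
    return read


def filter_reads(
    reads: Iterable[Read], min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[list[Read], QcReport]:
    """Trim trailing Ns, then drop reads containing N or too short.

    Returns the surviving reads (sample labels preserved) and a
    :class:`QcReport` whose counts are mutually consistent.
    """
    report = QcReport()
    survivors: list[Read] = []
    for read in reads:
        report.input_reads += 1
        trimmed = trim_trailing_n(read)
        if trimmed is not read:
            report.trailing_n_trimmed += 1
        if "N" in trimmed.sequence:
            report.discarded_n_reads += 1
            continue
        if len(trimmed.sequence) < min_length:
            report.discarded_short_reads += 1
            continue
        survivors.append(trimmed)
    return survivors, report


def filter_by_sample(
    reads_by_sample: dict[str, Sequence[Read]], min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[dict[str, list[Read]], dict[str, QcReport]]:
    """Apply :func:`filter_reads` per sample."""
    out: dict[str, list[Read]] = {}
    reports: dict[str, QcReport] = {}
    for sample, reads in reads_by_sample.items():
        out[sample], reports[sample] = filter_reads(reads, min_length=min_length)
    return out, reports
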
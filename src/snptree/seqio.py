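"""Read containers and FASTQ/FASTA I/O.

Reads are plain records: an identifier, an upper-case nucleotide string and
the label of the sample they were sequenced from.  Base qualities play no
role anywhere in the pipeline, so FASTQ output carries a constant
placeholder quality and FASTQ input discards the quality line.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Placeholder Phred quality written for every base (Q40).
PLACEHOLDER_QUALITY = "I"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """A sample-labelled short read; the unit of all downstream counting."""

    read_id: str
    sequence: str
    sample: str

    def __len__(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str) -> "Read":
        return replace(self, sequence=sequence)


def read_fastq(path: str | Path, sample: str) -> list[Read]:
    """Load a FASTQ file, labelling every record with *sample*."""
    out = []
    with open(path) as handle:
        for title, seq, _qual in FastqGeneralIterator(handle):
            out.append(Read(title.split()[0], seq.upper(), sample))
    return out


def write_fastq(path: str | Path, reads: Iterable[Read]) -> None:
    with open(path, "w") as handle:
        for r in reads:
            handle.write(
                f"@{r.read_id}\n{r.sequence}\n+\n{PLACEHOLDER_QUALITY * len(r.sequence)}\n"
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def iter_fastq_lazily(path: str | Path, sample: str) -> Iterator[Read]:
    """Streaming variant of :func:`read_fastq` for large files."""
    with open(path) as handle:
        for title, seq, _qual in FastqGeneralIterator(handle):
            yield Read(title.split()[0], seq.upper(), sample)
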
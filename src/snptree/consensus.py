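"""Per-sample consensus references.

Each sample's common-region reads are re-assembled on their own, and the
resulting contigs are polished to the per-position majority base over the
reads placed back on them.  These consensus sequences are the alignment
targets for every *other* sample's reads in the pairwise SNP stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .assembly import assemble_contigs, place_reads, validate_k
from .common import SampleReadSet
from .seqio import write_fasta

logger = logging.getLogger(__name__)

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII_TO_CODE[_b] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    """Map an ACGT string to uint8 codes 0..3."""
    return _ASCII_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode()


@dataclass
class ConsensusReference:
    """One sample's reference set: consensus contigs usable as targets."""

    sample_label: str
    sequences: list[tuple[str, str]]  # (ref_id, sequence)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    def write(self, path: str | Path) -> None:
        write_fasta(path, [(f"{self.sample_label}|{rid}", seq) for rid, seq in self.sequences])


def assemble_sample(
    read_set: SampleReadSet,
    k: int = 19,
    max_mismatches: int = 3,
    min_reference_length: int | None = None,
) -> ConsensusReference:
    """Assemble one sample's reads and call the majority consensus.

    The same assembler as the pooled stage is used; afterwards every
    position is set to the most frequent base among placed reads (ties go
    to the alphabetically first base and are counted in the log).
    References shorter than *min_reference_length* (default: the longest
    read, since shorter sequences cannot anchor a full alignment) are
    discarded.
    """
    if not read_set.reads:
        raise ValueError(f"sample {read_set.sample_label!r} has no common-region reads")
    validate_k(k, min(len(r.sequence) for r in read_set.reads))
    if min_reference_length is None:
        min_reference_length = max(len(r.sequence) for r in read_set.reads)

    contigs = assemble_contigs((r.sequence for r in read_set.reads), k)
    placements = place_reads(contigs, read_set.reads, k, max_mismatches=max_mismatches)

    piles: dict[str, np.ndarray] = {}
    seq_by_id = {c.contig_id: c.sequence for c in contigs}
    for p in placements:
        pile = piles.get(p.contig_id)
        if pile is None:
            pile = np.zeros((len(seq_by_id[p.contig_id]), 4), dtype=np.int32)
            piles[p.contig_id] = pile
        codes = seq_to_codes(p.oriented_sequence)
        pile[np.arange(p.offset, p.offset + len(codes)), codes] += 1

    ties = 0
    polished: list[str] = []
    for c in contigs:
        if len(c.sequence) < min_reference_length:
            continue
        pile = piles.get(c.contig_id)
        if pile is None:
            polished.append(c.sequence)  # no reads placed back; keep graph sequence
            continue
        depth = pile.sum(axis=1)
        top = pile.argmax(axis=1)  # argmax ties resolve to the first (alphabetical) base
        maxcount = pile.max(axis=1)
        ties += int(np.sum((depth > 0) & ((pile == maxcount[:, None]).sum(axis=1) > 1)))
        codes = seq_to_codes(c.sequence)
        covered = depth > 0
        codes[covered] = top[covered]
        polished.append(codes_to_seq(codes))
    if ties:
        logger.info("sample %s: %d consensus ties resolved alphabetically",
                    read_set.sample_label, ties)

    polished.sort(key=lambda s: (-len(s), s))
    refs = [(f"r{i:05d}", s) for i, s in enumerate(polished)]
    return ConsensusReference(read_set.sample_label, refs)
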
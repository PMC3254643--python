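"""Common-region discovery.

Reads from every sample are pooled and assembled together; only contigs
that attracted at least one read from every sample describe cDNA expressed
(and sequenced) in all of them, and only those regions are comparable
across the whole panel.  The retained contigs' reads are then handed back
to their samples as sample-specific read sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .assembly import Contig, ReadPlacement, assemble_contigs, place_reads, validate_k
from .seqio import Read

logger = logging.getLogger(__name__)

DEFAULT_POOLED_K = 19
DEFAULT_PLACEMENT_MISMATCHES = 3


@dataclass
class ContigWithMembership:
    """An assembled consensus plus the reads placed on it."""

    contig_id: str
    consensus: str
    placed_reads: list[ReadPlacement] = field(default_factory=list)

    @property
    def samples_present(self) -> frozenset[str]:
        return frozenset(p.read.sample for p in self.placed_reads)

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class SampleReadSet:
    sample_label: str
    reads: list[Read]

    def __len__(self) -> int:
        return len(self.reads)


def pooled_assemble(
    reads: Sequence[Read],
    k: int = DEFAULT_POOLED_K,
    max_mismatches: int = DEFAULT_PLACEMENT_MISMATCHES,
) -> list[ContigWithMembership]:
    """Assemble pooled reads and attach per-contig read membership.

    Each read is placed on at most one contig (best fit, ties to the lowest
    contig id); reads that fit nowhere are dropped.
    """
    if not reads:
        return []
    validate_k(k, min(len(r.sequence) for r in reads))
    contigs = assemble_contigs((r.sequence for r in reads), k)
    placements = place_reads(contigs, reads, k, max_mismatches=max_mismatches)
    by_contig: dict[str, list[ReadPlacement]] = {c.contig_id: [] for c in contigs}
    for p in placements:
        by_contig[p.contig_id].append(p)
    out = [
        ContigWithMembership(c.contig_id, c.sequence, by_contig[c.contig_id])
        for c in contigs
    ]
    n_placed = len(placements)
    logger.info(
        "pooled assembly: %d contigs, %d/%d reads placed", len(out), n_placed, len(reads)
    )
    return out


def filter_common_contigs(
    contigs: Sequence[ContigWithMembership], all_samples: Iterable[str]
) -> tuple[list[ContigWithMembership], float]:
    """Keep contigs whose membership covers every sample.

    Returns the retained contigs and the fraction of placed reads they
    retain (0.0 when nothing was placed at all).
    """
    wanted = frozenset(all_samples)
    if not wanted:
        raise ValueError("all_samples must be non-empty")
    retained = [c for c in contigs if c.samples_present >= wanted]
    total = sum(len(c.placed_reads) for c in contigs)
    kept = sum(len(c.placed_reads) for c in retained)
    fraction = kept / total if total else 0.0
    logger.info(
        "common-region filter: %d/%d contigs, %.2f%% of placed reads retained",
        len(retained), len(contigs), 100.0 * fraction,
    )
    return retained, fraction


def split_by_sample(contigs: Sequence[ContigWithMembership]) -> list[SampleReadSet]:
    """Break retained contigs' reads into sample-specific read sets.

    The read multiset is preserved exactly: every placed read appears in
    precisely one set, under its own sample label.
    """
    by_sample: dict[str, list[Read]] = {}
    for contig in contigs:
        for p in contig.placed_reads:
            by_sample.setdefault(p.read.sample, []).append(p.read)
    return [SampleReadSet(s, by_sample[s]) for s in sorted(by_sample)]


def write_membership_table(contigs: Sequence[ContigWithMembership], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tread_id\tsample\toffset\tstrand\n")
        for c in contigs:
            for p in c.placed_reads:
                fh.write(f"{c.contig_id}\t{p.read.read_id}\t{p.read.sample}\t{p.offset}\t{p.strand}\n")
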
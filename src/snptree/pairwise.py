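"""Directed pairwise SNP calling.

For an ordered sample pair (A -> B), sample A's common-region reads are
aligned gaplessly to sample B's consensus references with a seed-and-extend
strategy.  A SNP is a reference site where the ploidy-aware consensus of
A's aligned reads differs from B's reference base.  The distance statistic
is SNPs per *aligned base* — the denominator sums the lengths of all
aligned reads, not the reference span — which deliberately up-weights SNPs
contributed by samples with few reads.

Ploidy enters through the minimum allele fraction: with ploidy p, a single
homoeologous copy contributes an expected 1/p of the reads, so a base must
reach at least ``1/(2p)`` of the pile-up (and a minimum depth) before it
can be called as the consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .consensus import ConsensusReference, seq_to_codes
from .seqio import Read, revcomp

logger = logging.getLogger(__name__)

DEFAULT_SEED_LENGTH = 20
DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MIN_DEPTH = 3
_BASES = "ACGT"


@dataclass(frozen=True)
class ReadAlignment:
    """A gapless, full-length placement of one read on one reference."""

    read_id: str
    ref_id: str
    ref_offset: int  # 0-based
    strand: str
    mismatch_count: int
    sequence: str  # read sequence in reference orientation

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PairPileup:
    """Vectorised pile-up of one directed pair, reusable across bootstrap draws.

    ``site`` / ``base`` / ``read_index`` hold one entry per aligned read
    base, with sites indexed in a concatenation of all reference sequences.
    """

    ref_codes: np.ndarray        # (G,) uint8, concatenated reference bases
    site: np.ndarray             # (M,) int64
    base: np.ndarray             # (M,) uint8
    read_index: np.ndarray       # (M,) int32
    read_lengths: np.ndarray     # (R,) int32
    site_bounds: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.read_lengths)


@dataclass
class DirectedSnpResult:
    """SNP count and aligned-base total for an ordered sample pair."""

    query_sample: str
    reference_sample: str
    snp_count: int | None
    aligned_bases: int | None
    _rate: float | None = None
    pileup: PairPileup | None = field(default=None, repr=False)

    @classmethod
    def from_rate(cls, query: str, reference: str, rate: float) -> "DirectedSnpResult":
        """Wrap an externally reported SNPs-per-aligned-base rate."""
        return cls(query, reference, None, None, _rate=float(rate))

    @property
    def snp_rate(self) -> float:
        if self._rate is not None:
            return self._rate
        if not self.aligned_bases:
            raise ValueError(
                f"no alignable reads for pair {self.query_sample}->{self.reference_sample}"
            )
        return self.snp_count / self.aligned_bases


def _build_seed_index(
    reference: ConsensusReference, seed_length: int
) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, (_rid, seq) in enumerate(reference.sequences):
        for i in range(len(seq) - seed_length + 1):
            index.setdefault(seq[i : i + seed_length], []).append((ri, i))
    return index


def align_reads(
    reads: Sequence[Read],
    reference: ConsensusReference,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    seed_length: int = DEFAULT_SEED_LENGTH,
    _index: dict | None = None,
) -> list[ReadAlignment]:
    """Seed-and-extend alignment of reads against one sample's references.

    The first *seed_length* bases of the read (on each strand) must match
    exactly; candidate placements are extended gaplessly over the full read
    and the one with the fewest mismatches is kept.  A tie between distinct
    best placements leaves the read unmapped (logged), which avoids paralogs
    inflating the SNP count.
    """
    if not reference.sequences:
        raise ValueError("empty reference set")
    index = _index if _index is not None else _build_seed_index(reference, seed_length)
    seqs = [s for _rid, s in reference.sequences]
    rids = [rid for rid, _s in reference.sequences]

    out: list[ReadAlignment] = []
    ambiguous = 0
    for read in reads:
        if len(read.sequence) < seed_length:
            continue
        candidates: list[tuple[int, int, int, int]] = []
        best_mm = max_mismatches
        for strand_rank, q in enumerate((read.sequence, revcomp(read.sequence))):
            for ri, pos in index.get(q[:seed_length], ()):  # seed must match exactly
                ref_seq = seqs[ri]
                end = pos + len(q)
                if end > len(ref_seq):
                    continue
                window = ref_seq[pos:end]
                if q == window:
                    mm = 0
                else:
                    mm = 0
                    for a, b in zip(q, window):
                        if a != b:
                            mm += 1
                            if mm > best_mm:
                                break
                if mm <= best_mm:
                    candidates.append((mm, ri, pos, strand_rank))
                    best_mm = min(best_mm, mm)
        if not candidates:
            continue
        best = min(candidates)
        tied = [
            c for c in candidates
            if c[0] == best[0] and (c[1], c[2]) != (best[1], best[2])
        ]
        if tied:
            ambiguous += 1
            continue
        mm, ri, pos, strand_rank = best
        strand = "+" if strand_rank == 0 else "-"
        q = read.sequence if strand == "+" else revcomp(read.sequence)
        out.append(ReadAlignment(read.read_id, rids[ri], pos, strand, mm, q))
    if ambiguous:
        logger.info("alignment: %d reads dropped as ambiguous best placements", ambiguous)
    return out


def call_site_consensus(
    counts: Mapping[str, int | float],
    ploidy: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_fraction: float | None = None,
) -> str | None:
    """Ploidy-aware consensus for a single pile-up column.

    Returns the most frequent base when the depth reaches *min_depth* and
    its fraction reaches *min_allele_fraction* (default ``1/(2*ploidy)``:
    one homoeolog's worth of support must not flip the call); otherwise
    ``None`` (no-call).  Frequency ties resolve alphabetically.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if min_allele_fraction is None:
        min_allele_fraction = 1.0 / (2 * ploidy)
    depth = sum(counts.get(b, 0) for b in _BASES)
    if depth < min_depth:
        return None
    top = max(_BASES, key=lambda b: counts.get(b, 0))
    if counts.get(top, 0) < min_allele_fraction * depth - 1e-9:
        return None
    return top


def build_pair_pileup(
    alignments: Sequence[ReadAlignment], reference: ConsensusReference
) -> PairPileup:
    """Assemble the vectorised pile-up arrays for one directed pair."""
    offsets: dict[str, int] = {}
    bounds: list[tuple[str, int, int]] = []
    total = 0
    ref_parts = []
    for rid, seq in reference.sequences:
        offsets[rid] = total
        bounds.append((rid, total, total + len(seq)))
        total += len(seq)
        ref_parts.append(seq_to_codes(seq))
    ref_codes = (
        np.concatenate(ref_parts) if ref_parts else np.zeros(0, dtype=np.uint8)
    )

    sites, bases, read_idx = [], [], []
    lengths = np.zeros(len(alignments), dtype=np.int32)
    for i, aln in enumerate(alignments):
        L = len(aln.sequence)
        lengths[i] = L
        start = offsets[aln.ref_id] + aln.ref_offset
        sites.append(np.arange(start, start + L, dtype=np.int64))
        bases.append(seq_to_codes(aln.sequence))
        read_idx.append(np.full(L, i, dtype=np.int32))
    if alignments:
        site = np.concatenate(sites)
        base = np.concatenate(bases)
        ridx = np.concatenate(read_idx)
    else:
        site = np.zeros(0, dtype=np.int64)
        base = np.zeros(0, dtype=np.uint8)
        ridx = np.zeros(0, dtype=np.int32)
    return PairPileup(ref_codes, site, base, ridx, lengths, bounds)


def snps_from_pileup(
    pileup: PairPileup,
    ploidy: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_fraction: float | None = None,
    read_weights: np.ndarray | None = None,
) -> tuple[int, float]:
    """Count consensus-vs-reference SNP sites and aligned bases.

    *read_weights* (bootstrap multiplicities) default to 1 per read.
    Returns ``(snp_count, aligned_bases)``.
    """
    if min_allele_fraction is None:
        min_allele_fraction = 1.0 / (2 * ploidy)
    G = len(pileup.ref_codes)
    if read_weights is None:
        w = np.ones(len(pileup.read_lengths), dtype=np.float64)
    else:
        w = np.asarray(read_weights, dtype=np.float64)
    aligned_bases = float(w @ pileup.read_lengths)
    if pileup.site.size == 0 or G == 0:
        return 0, aligned_bases
    flat = pileup.site * 4 + pileup.base
    counts = np.bincount(flat, weights=w[pileup.read_index], minlength=4 * G)
    counts = counts.reshape(G, 4)
    depth = counts.sum(axis=1)
    top = counts.argmax(axis=1)  # ties -> lowest code = alphabetical
    topc = counts.max(axis=1)
    called = (depth >= min_depth) & (topc >= min_allele_fraction * depth - 1e-9)
    snps = called & (top != pileup.ref_codes)
    return int(np.count_nonzero(snps)), aligned_bases


def snp_site_table(
    pileup: PairPileup,
    ploidy: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_fraction: float | None = None,
) -> list[tuple[str, int, str, str, int]]:
    """Per-site SNP list: (ref_id, 0-based position, ref base, consensus, depth)."""
    if min_allele_fraction is None:
        min_allele_fraction = 1.0 / (2 * ploidy)
    G = len(pileup.ref_codes)
    if G == 0 or pileup.site.size == 0:
        return []
    counts = np.bincount(pileup.site * 4 + pileup.base, minlength=4 * G).reshape(G, 4)
    depth = counts.sum(axis=1)
    top = counts.argmax(axis=1)
    topc = counts.max(axis=1)
    called = (depth >= min_depth) & (topc >= min_allele_fraction * depth - 1e-9)
    snps = np.flatnonzero(called & (top != pileup.ref_codes))
    rows = []
    for g in snps:
        for rid, lo, hi in pileup.site_bounds:
            if lo <= g < hi:
                rows.append((rid, int(g - lo), _BASES[pileup.ref_codes[g]],
                             _BASES[top[g]], int(depth[g])))
                break
    return rows


def count_directed_snps(
    alignments: Sequence[ReadAlignment],
    reference: ConsensusReference,
    ploidy: int,
    query_sample: str = "",
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_fraction: float | None = None,
) -> DirectedSnpResult:
    """Directed SNP result for *query_sample*'s alignments on *reference*."""
    pileup = build_pair_pileup(alignments, reference)
    snp_count, aligned = snps_from_pileup(
        pileup, ploidy, min_depth=min_depth, min_allele_fraction=min_allele_fraction
    )
    if aligned == 0:
        raise ValueError(
            f"no alignable reads for pair {query_sample}->{reference.sample_label}"
        )
    return DirectedSnpResult(
        query_sample, reference.sample_label, snp_count, int(aligned), pileup=pileup
    )


def all_pairs(
    read_sets: Mapping[str, Sequence[Read]],
    references: Mapping[str, ConsensusReference],
    ploidy: Mapping[str, int] | int = 3,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    seed_length: int = DEFAULT_SEED_LENGTH,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_fraction: float | None = None,
) -> list[DirectedSnpResult]:
    """All S*(S-1) directed SNP results over the sample panel.

    *ploidy* is the query sample's: the consensus of a triploid's reads
    must tolerate a one-third minor-allele fraction regardless of which
    reference it is aligned to.
    """
    samples = sorted(read_sets)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if set(samples) != set(references):
        raise ValueError("read sets and references cover different samples")
    ploidy_of = (
        (lambda s: ploidy[s]) if isinstance(ploidy, Mapping) else (lambda s: ploidy)
    )
    results: list[DirectedSnpResult] = []
    for ref_sample in samples:
        reference = references[ref_sample]
        index = _build_seed_index(reference, seed_length)
        for query_sample in samples:
            if query_sample == ref_sample:
                continue
            try:
                alns = align_reads(
                    read_sets[query_sample], reference,
                    max_mismatches=max_mismatches, seed_length=seed_length,
                    _index=index,
                )
                results.append(
                    count_directed_snps(
                        alns, reference, ploidy_of(query_sample),
                        query_sample=query_sample, min_depth=min_depth,
                        min_allele_fraction=min_allele_fraction,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"pair {query_sample}->{ref_sample}: {exc}") from exc
    return results


def write_rate_table(
    results: Sequence[DirectedSnpResult], path: str | Path, labels: Sequence[str] | None = None
) -> None:
    """Square table of directed rates: rows = query sample, columns = reference."""
    if labels is None:
        seen = dict.fromkeys(
            [r.query_sample for r in results] + [r.reference_sample for r in results]
        )
        labels = list(seen)
    rate = {(r.query_sample, r.reference_sample): r.snp_rate for r in results}
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for q in labels:
            cells = [
                "-" if q == ref else f"{rate[(q, ref)]:.9g}" for ref in labels
            ]
            fh.write(q + "\t" + "\t".join(cells) + "\n")
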
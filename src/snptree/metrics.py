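"""Transcript-assembly evaluation metrics.

For transcript data, N50 is a poor optimisation target: ideal contigs
should match cDNA lengths, coverage is uneven by design, and the single
longest contig is insensitive to k.  The selection metric used here is the
mean length of the 100 longest contigs across a sweep of k-mer sizes; the
independent validation metric is the number of reference-transcript bases
covered by non-overlapping, 100%-identity alignments of the contigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .assembly import Contig, assemble_contigs
from .seqio import Read, revcomp

logger = logging.getLogger(__name__)


def n50(contig_lengths: Sequence[int]) -> int:
    """Largest L such that contigs >= L hold at least half the total bases."""
    if not contig_lengths:
        raise ValueError("empty length list")
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2.0
    acc = 0
    for L in lengths:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def top_k_mean(contig_lengths: Sequence[int], k: int = 100) -> float:
    """Mean of the k largest contig lengths (all of them if fewer than k)."""
    if not contig_lengths:
        raise ValueError("empty length list")
    top = sorted(contig_lengths, reverse=True)[:k]
    return sum(top) / len(top)


@dataclass(frozen=True)
class AssemblyMetricsRow:
    k: int
    n50: int
    longest: int
    total_length: int
    top100_mean: float

    def as_tsv_row(self) -> str:
        return f"{self.k}\t{self.top100_mean:.1f}\t{self.longest}\t{self.n50}\t{self.total_length}"


def metrics_for_contigs(contigs: Sequence[Contig], k: int, top: int = 100) -> AssemblyMetricsRow:
    lengths = [len(c) for c in contigs]
    return AssemblyMetricsRow(
        k=k,
        n50=n50(lengths),
        longest=max(lengths),
        total_length=sum(lengths),
        top100_mean=top_k_mean(lengths, top),
    )


def k_sweep(
    reads: Sequence[Read | str],
    k_values: Sequence[int],
    top: int = 100,
) -> tuple[list[AssemblyMetricsRow], int, dict[int, list[Contig]]]:
    """Assemble at every k and pick the k maximising the top-*top* mean.

    Invalid k values (even, or longer than the shortest read) are skipped
    with a warning; ties in the selection metric go to the smallest k.
    Returns (rows, selected_k, contigs per k).
    """
    if len(k_values) < 2:
        raise ValueError("need at least two k values to sweep")
    seqs = [r.sequence if isinstance(r, Read) else r for r in reads]
    min_len = min((len(s) for s in seqs), default=0)
    rows: list[AssemblyMetricsRow] = []
    contigs_by_k: dict[int, list[Contig]] = {}
    for k in k_values:
        if k % 2 == 0 or k < 15 or k > min_len:
            logger.warning("k=%d invalid for these reads; skipped", k)
            continue
        contigs = assemble_contigs(seqs, k)
        if not contigs:
            logger.warning("k=%d produced no contigs; skipped", k)
            continue
        contigs_by_k[k] = contigs
        rows.append(metrics_for_contigs(contigs, k, top))
    if not rows:
        raise ValueError("no valid k values")
    selected = min(rows, key=lambda r: (-r.top100_mean, r.k)).k
    return rows, selected, contigs_by_k


@dataclass
class IdentityCoverage:
    """Reference bases covered by accepted non-overlapping exact matches."""

    covered_bases: int
    intervals: list[tuple[str, int, int]]  # (ref_id, start, end) 0-based half-open

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for rid, start, end in sorted(self.intervals):
                fh.write(f"{rid}\t{start}\t{end}\n")


def _maximal_exact_matches(
    contig: str, refs: Mapping[str, str], index: Mapping[str, list[tuple[str, int]]],
    min_match: int,
) -> set[tuple[int, str, int, int]]:
    """(length, ref_id, ref_start, ref_end) of left/right-maximal matches."""
    out: set[tuple[int, str, int, int]] = set()
    L = min_match
    n = len(contig)
    for i in range(n - L + 1):
        hits = index.get(contig[i : i + L])
        if not hits:
            continue
        for rid, j in hits:
            ref = refs[rid]
            if i > 0 and j > 0 and contig[i - 1] == ref[j - 1]:
                continue  # not left-maximal; found from an earlier anchor
            ext = L
            while i + ext < n and j + ext < len(ref) and contig[i + ext] == ref[j + ext]:
                ext += 1
            out.add((ext, rid, j, j + ext))
    return out


def identity_coverage(
    contigs: Iterable[Contig | str],
    reference_transcripts: Mapping[str, str] | Sequence[tuple[str, str]],
    min_match: int = 50,
) -> IdentityCoverage:
    """Greedy non-overlapping 100%-identity coverage of the references.

    All maximal exact matches of length >= *min_match* between the contigs
    (either strand) and the references are collected, then accepted in
    decreasing length order; a match overlapping an already accepted
    interval on the same reference is discarded entirely.
    """
    if min_match < 20:
        raise ValueError("min_match must be >= 20")
    refs = dict(reference_transcripts)
    if not refs:
        raise ValueError("empty reference set")
    index: dict[str, list[tuple[str, int]]] = {}
    for rid, seq in refs.items():
        for j in range(len(seq) - min_match + 1):
            index.setdefault(seq[j : j + min_match], []).append((rid, j))

    matches: set[tuple[int, str, int, int]] = set()
    for c in contigs:
        seq = c.sequence if isinstance(c, Contig) else c
        for s in (seq, revcomp(seq)):
            matches |= _maximal_exact_matches(s, refs, index, min_match)

    accepted: dict[str, list[tuple[int, int]]] = {}
    covered = 0
    for length, rid, start, end in sorted(
        matches, key=lambda m: (-m[0], m[1], m[2], m[3])
    ):
        taken = accepted.setdefault(rid, [])
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        covered += length
    intervals = [(rid, s, e) for rid, ivs in accepted.items() for s, e in ivs]
    return IdentityCoverage(covered, sorted(intervals))


def write_metrics_table(rows: Sequence[AssemblyMetricsRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("k\ttop100_mean\tlongest\tn50\ttotal_length\n")
        for row in sorted(rows, key=lambda r: r.k):
            fh.write(row.as_tsv_row() + "\n")
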
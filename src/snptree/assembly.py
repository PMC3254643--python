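"""Simplified de Bruijn transcript assembler.

The assembler is deliberately minimal and fully deterministic:

* k-mers from both strands of every read form the node set (odd k only, so
  no k-mer is its own reverse complement and the graph splits cleanly into
  strand twins);
* dead-end tips shorter than ``2k`` nodes are trimmed (sequencing errors in
  short reads almost always produce tips rather than rejoining paths);
* simple bubbles — two or more internally unbranched paths between the same
  divergence and junction nodes — are popped by keeping the highest-coverage
  arm.  Popping is iterated so chains of overlapping variant bubbles resolve
  innermost-first;
* maximal unbranched paths are compressed into contigs, strand twins are
  deduplicated to the lexicographically smaller sequence, and contigs are
  numbered by (length desc, sequence) so identifiers are reproducible;
* reads are optionally placed back on contigs by anchoring any exact k-mer
  and accepting the best bounded-mismatch gapless fit.

No coverage cutoff or expected-coverage parameter is applied: transcript
data has genuinely uneven depth, so coverage is never used to discard
sequence, only to arbitrate bubble arms.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import Read, revcomp

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPlacement:
    """A read anchored on a contig: gapless, full-length, few mismatches."""

    read: Read
    contig_id: str
    offset: int
    strand: str  # '+' or '-'
    mismatches: int

    @property
    def oriented_sequence(self) -> str:
        return self.read.sequence if self.strand == "+" else revcomp(self.read.sequence)


def validate_k(k: int, min_read_length: int | None = None) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if k < 15:
        raise ValueError(f"k must be >= 15, got {k}")
    if min_read_length is not None and k > min_read_length:
        raise ValueError(f"k={k} exceeds shortest read length {min_read_length}")


class DeBruijnGraph:
    """k-mer coverage graph over both strands; edges are implicit overlaps."""

    def __init__(self, k: int):
        if k % 2 == 0 or k < 3:
            raise ValueError(f"k must be odd and >= 3, got {k}")
        self.k = k
        self.cov: dict[str, int] = {}

    # -- construction -------------------------------------------------
    def add_sequence(self, seq: str) -> None:
        k = self.k
        cov = self.cov
        for s in (seq, revcomp(seq)):
            if "N" in s:
                self._add_split_on_n(s)
                continue
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                cov[km] = cov.get(km, 0) + 1

    def _add_split_on_n(self, s: str) -> None:
        k, cov = self.k, self.cov
        for part in s.split("N"):
            for i in range(len(part) - k + 1):
                km = part[i : i + k]
                cov[km] = cov.get(km, 0) + 1

    # -- topology helpers ---------------------------------------------
    def successors(self, km: str) -> list[str]:
        suf = km[1:]
        cov = self.cov
        return [suf + b for b in _BASES if suf + b in cov]

    def predecessors(self, km: str) -> list[str]:
        pre = km[:-1]
        cov = self.cov
        return [b + pre for b in _BASES if b + pre in cov]

    def _remove_with_twins(self, nodes: Iterable[str]) -> None:
        cov = self.cov
        for n in nodes:
            cov.pop(n, None)
            cov.pop(revcomp(n), None)

    # -- simplification -----------------------------------------------
    def trim_tips(self, max_rounds: int = 8) -> int:
        """Remove dead-end paths shorter than 2k nodes hanging off junctions."""
        limit = 2 * self.k
        removed_total = 0
        for _ in range(max_rounds):
            to_remove: set[str] = set()
            for node in list(self.cov):
                if node in to_remove or node not in self.cov:
                    continue
                if self.successors(node):
                    continue
                # walk back along the unbranched chain ending at this dead end
                path = [node]
                cur = node
                attached = False
                while len(path) <= limit:
                    preds = self.predecessors(cur)
                    if len(preds) != 1:
                        break
                    p = preds[0]
                    if len(self.successors(p)) != 1:
                        attached = True  # p is a junction the tip hangs off
                        break
                    path.append(p)
                    cur = p
                if attached and len(path) < limit:
                    to_remove.update(path)
            if not to_remove:
                break
            self._remove_with_twins(to_remove)
            removed_total += len(to_remove)
        return removed_total

    def _arm_strength(self, interior: list[str]) -> tuple[int, str]:
        """Ordering key for competing bubble arms: (coverage, canonical seq).

        The canonical-sequence tie-break is identical for a path and its
        strand twin, so both twins of a bubble resolve the same way.
        """
        seq = interior[0] + "".join(n[-1] for n in interior[1:]) if interior else ""
        canon = min(seq, revcomp(seq)) if seq else ""
        return (sum(self.cov.get(n, 0) for n in interior), canon)

    def _merge_one_bubble(self, entrance: str, path_limit: int) -> int:
        """Find the nearest pair of reconverging paths out of *entrance*
        and delete the weaker arm's private nodes.  Returns nodes removed.
        """
        parent: dict[str, str | None] = {entrance: None}
        depth = {entrance: 0}
        queue = deque([entrance])
        merge: tuple[str, str] | None = None
        while queue and merge is None:
            v = queue.popleft()
            if depth[v] >= path_limit:
                continue
            for c in sorted(self.successors(v)):
                if c == entrance:
                    continue
                if c in parent:
                    merge = (c, v)  # second path into c: a bubble closes here
                    break
                parent[c] = v
                depth[c] = depth[v] + 1
                queue.append(c)
        if merge is None:
            return 0
        join, via = merge

        def chain(x: str | None) -> list[str]:
            out: list[str] = []
            while x is not None and x != entrance:
                out.append(x)
                x = parent[x]
            return out[::-1]

        arm1 = chain(parent[join])
        arm2 = chain(via)
        if set(arm1) & set(arm2):
            return 0  # paths share a prefix: the real divergence is downstream
        if not arm1 or not arm2:
            return 0
        loser = min(arm1, arm2, key=self._arm_strength)
        winner = arm2 if loser is arm1 else arm1
        private = [n for n in loser if n not in winner]
        if not private:
            return 0
        self._remove_with_twins(private)
        return len(private)

    def pop_bubbles(self, max_rounds: int = 40, path_limit: int | None = None) -> int:
        """Iteratively merge bubbles, keeping the higher-coverage arm.

        A breadth-first search from every branching node finds the nearest
        reconvergence of two outgoing paths (a variant or error bubble,
        however staggered with its neighbours); the weaker arm and its
        strand twin are deleted.  Iterating to a fixed point lets dense
        chains of overlapping bubbles resolve one arm at a time, and tips
        exposed by arm removal are trimmed between rounds.  Entirely
        deterministic: nodes and successors are processed in sorted order
        and coverage ties prefer the lexicographically smaller canonical
        arm sequence.
        """
        if path_limit is None:
            path_limit = 5 * self.k
        popped_total = 0
        for _ in range(max_rounds):
            removed_this_round = 0
            for u in sorted(self.cov):
                if u not in self.cov:
                    continue
                while u in self.cov and len(self.successors(u)) >= 2:
                    removed = self._merge_one_bubble(u, path_limit)
                    if removed == 0:
                        break
                    removed_this_round += removed
            if removed_this_round == 0:
                break
            popped_total += removed_this_round
            self.trim_tips(max_rounds=2)
        return popped_total

    # -- contig extraction --------------------------------------------
    def unitigs(self) -> list[str]:
        """Compress maximal unbranched paths into sequences (both strands)."""
        cov = self.cov

        def is_start(n: str) -> bool:
            preds = self.predecessors(n)
            if len(preds) != 1:
                return True
            return len(self.successors(preds[0])) != 1

        visited: set[str] = set()
        out: list[str] = []
        for n in sorted(cov):
            if n in visited or not is_start(n):
                continue
            path = [n]
            visited.add(n)
            cur = n
            while True:
                succ = self.successors(cur)
                if len(succ) != 1:
                    break
                nxt = succ[0]
                if len(self.predecessors(nxt)) != 1 or nxt in visited:
                    break
                path.append(nxt)
                visited.add(nxt)
                cur = nxt
            out.append(path[0] + "".join(p[-1] for p in path[1:]))
        # isolated cycles: every node internal; break at the smallest node
        leftovers = sorted(set(cov) - visited)
        for n in leftovers:
            if n in visited:
                continue
            path = [n]
            visited.add(n)
            cur = n
            while True:
                succ = self.successors(cur)
                if len(succ) != 1:
                    break
                nxt = succ[0]
                if nxt in visited:
                    break
                path.append(nxt)
                visited.add(nxt)
                cur = nxt
            out.append(path[0] + "".join(p[-1] for p in path[1:]))
        return out


def assemble_contigs(
    sequences: Iterable[str],
    k: int,
    *,
    trim_tips: bool = True,
    pop_bubbles: bool = True,
    min_length: int | None = None,
) -> list[Contig]:
    """Assemble raw sequences into deduplicated, deterministically-named contigs."""
    graph = DeBruijnGraph(k)
    for seq in sequences:
        if len(seq) >= k:
            graph.add_sequence(seq)
    if not graph.cov:
        return []
    if trim_tips:
        graph.trim_tips()
    if pop_bubbles:
        graph.pop_bubbles()
        graph.trim_tips()
    seen: set[str] = set()
    seqs: list[str] = []
    for u in graph.unitigs():
        canon = min(u, revcomp(u))
        if canon in seen:
            continue
        seen.add(canon)
        if min_length is not None and len(canon) < min_length:
            continue
        seqs.append(canon)
    seqs.sort(key=lambda s: (-len(s), s))
    return [Contig(f"c{i:05d}", s) for i, s in enumerate(seqs)]


def _hamming_capped(a: str, b: str, cap: int) -> int:
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def place_reads(
    contigs: Sequence[Contig],
    reads: Sequence[Read],
    k: int,
    max_mismatches: int = 3,
) -> list[ReadPlacement]:
    """Anchor each read on at most one contig.

    Any exact k-mer shared between the read (either strand) and a contig
    proposes a gapless full-length placement; the best placement (fewest
    mismatches, then lowest contig id, offset, then '+' strand) wins,
    provided it has at most *max_mismatches* mismatches.  Unplaceable reads
    are silently dropped from the result.
    """
    index: dict[str, list[tuple[int, int]]] = {}
    contig_seqs = [c.sequence for c in contigs]
    for ci, seq in enumerate(contig_seqs):
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((ci, i))

    placements: list[ReadPlacement] = []
    for read in reads:
        seq = read.sequence
        if len(seq) < k:
            continue
        best: tuple[int, int, int, int] | None = None
        seen: set[tuple[int, int, int]] = set()
        for strand_rank, (strand, s) in enumerate((("+", seq), ("-", revcomp(seq)))):
            L = len(s)
            for j in range(L - k + 1):
                hits = index.get(s[j : j + k])
                if not hits:
                    continue
                for ci, pos in hits:
                    start = pos - j
                    if start < 0 or start + L > len(contig_seqs[ci]):
                        continue
                    key = (ci, start, strand_rank)
                    if key in seen:
                        continue
                    seen.add(key)
                    mm = _hamming_capped(s, contig_seqs[ci][start : start + L], max_mismatches)
                    if mm > max_mismatches:
                        continue
                    cand = (mm, ci, start, strand_rank)
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            mm, ci, start, strand_rank = best
            placements.append(
                ReadPlacement(
                    read=read,
                    contig_id=contigs[ci].contig_id,
                    offset=start,
                    strand="+" if strand_rank == 0 else "-",
                    mismatches=mm,
                )
            )
    return placements
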
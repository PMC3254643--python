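"""Distance-matrix construction, neighbor joining, bootstrap support.

The distance between two samples is the mean of their two directed
SNPs-per-aligned-base rates, which symmetrises the asymmetric table of
directed rates.  Trees are inferred with classical neighbor joining
(Saitou-Nei Q criterion); node support comes from resampling each directed
pair's aligned reads with replacement, recomputing the rate matrix, and
taking the majority-rule consensus of the replicate NJ trees.

All tie-breaks are deterministic: Q-criterion ties join the
lexicographically smallest label pair, and negative branch lengths are
clamped to zero (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .pairwise import DirectedSnpResult, snps_from_pileup

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 8) -> float:
    """Round half away from zero (what most report formatters do)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DistanceMatrix:
    """Symmetric SNP-rate distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if np.any(v < 0):
            raise ValueError("negative distances")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def lower_triangle_tsv(self, ndigits: int = 8) -> str:
        """Lower-triangle report with half-away rounding at *ndigits*."""
        lines = ["\t" + "\t".join(self.labels)]
        for i, lab in enumerate(self.labels):
            cells = [f"{round_half_away(self.values[i, j], ndigits):.{ndigits}f}"
                     for j in range(i)]
            cells.append("-")
            lines.append(lab + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{self.values[i, j]:.10f}" for j in range(len(self.labels)))
                fh.write(f"{lab:<10s} {row}\n")


def build_distance_matrix(
    directed: Iterable[DirectedSnpResult] | Mapping[tuple[str, str], float],
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Mean-of-reciprocals distance matrix from directed SNP rates.

    Both directions must be present for every unordered pair.  *labels*
    fixes the row/column order (default: order of first appearance).
    """
    if isinstance(directed, Mapping):
        rate = {k: float(v) for k, v in directed.items()}
    else:
        rate = {(r.query_sample, r.reference_sample): r.snp_rate for r in directed}
    if labels is None:
        seen: dict[str, None] = {}
        for q, r in rate:
            seen.setdefault(q)
            seen.setdefault(r)
        labels = list(seen)
    labels = list(labels)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            if (a, b) not in rate or (b, a) not in rate:
                raise ValueError(f"missing direction for pair ({a}, {b})")
            d = 0.5 * (rate[(a, b)] + rate[(b, a)])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


@dataclass
class SupportTree:
    """Unrooted tree with branch lengths and optional per-split supports."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, each written as the side omitting the
        alphabetically first leaf."""
        labels = self.labels
        if len(labels) < 4:
            return set()
        all_set = frozenset(labels)
        ref = labels[0]
        out: set[frozenset] = set()
        for node in self.tree.postorder_node_iter():
            if node is self.tree.seed_node or node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            side = all_set - below if ref in below else below
            if 1 < len(side) < len(labels) - 1:
                out.add(side)
        return out

    def path_distance(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        tns = self.tree.taxon_namespace
        return pdm.distance(tns.get_taxon(a), tns.get_taxon(b))


def robinson_foulds(t1: SupportTree, t2: SupportTree) -> int:
    """Count of nontrivial splits present in one tree but not the other."""
    if t1.labels != t2.labels:
        raise ValueError("trees have different leaf sets")
    return len(t1.splits() ^ t2.splits())


def neighbor_joining(dm: DistanceMatrix) -> SupportTree:
    """Classical neighbor joining; exact on additive matrices.

    Deterministic: Q ties join the pair whose (sorted) smallest-leaf labels
    compare lowest; negative branch lengths are clamped to 0 with the
    deficit logged.
    """
    labels = dm.labels
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(labels)
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    nodes: dict[int, dendropy.Node] = {}
    key: dict[int, str] = {}
    for i, lab in enumerate(labels):
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nodes[i] = nd
        key[i] = lab
    D: dict[int, dict[int, float]] = {
        i: {j: float(dm.values[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    active = list(range(n))
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        best_pair = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * D[i][j] - r[i] - r[j]
                tie_key = tuple(sorted((key[i], key[j])))
                cand = (q, tie_key)
                if best is None or cand < best:
                    best = cand
                    best_pair = (i, j)
        i, j = best_pair
        dij = D[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li), clamp(lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        u = next_id
        next_id += 1
        nodes[u] = parent
        key[u] = min(key[i], key[j])
        D[u] = {}
        for k_ in active:
            if k_ in (i, j):
                continue
            duk = max(0.0, 0.5 * (D[i][k_] + D[j][k_] - dij))
            D[u][k_] = duk
            D[k_][u] = duk
        active = [a for a in active if a not in (i, j)] + [u]

    a, b, c = sorted(active, key=lambda x: key[x])
    la = clamp(0.5 * (D[a][b] + D[a][c] - D[b][c]))
    lb = clamp(0.5 * (D[a][b] + D[b][c] - D[a][c]))
    lc = clamp(0.5 * (D[a][c] + D[b][c] - D[a][b]))
    center = dendropy.Node()
    for x, lx in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[x])
        nodes[x].edge.length = lx

    if clamped:
        logger.info("neighbor joining: clamped %.3g of negative branch length", clamped)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return SupportTree(tree)


def _check_shared_leaves(trees: Sequence[SupportTree]) -> list[str]:
    labels = trees[0].labels
    for t in trees[1:]:
        if t.labels != labels:
            raise ValueError("inconsistent leaf sets across trees")
    return labels


def majority_rule_consensus(trees: Sequence[SupportTree]) -> SupportTree:
    """Strict-majority (>50%) consensus with percentage supports.

    Splits at exactly 50% are excluded.  The retained splits are pairwise
    compatible by construction, so they assemble into a single tree.
    """
    if not trees:
        raise ValueError("no trees given")
    labels = _check_shared_leaves(trees)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    ntrees = len(trees)
    majority = {s: c for s, c in counts.items() if c * 2 > ntrees}
    supports = {s: 100.0 * c / ntrees for s, c in majority.items()}
    return _tree_from_splits(labels, supports)


def _tree_from_splits(labels: Sequence[str], supports: Mapping[frozenset, float]) -> SupportTree:
    """Build an unrooted tree from a laminar family of canonical splits."""
    tns = dendropy.TaxonNamespace(list(labels))
    root = dendropy.Node()
    leafset: dict[int, frozenset] = {}
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nd.edge.length = None
        root.add_child(nd)
        leafset[id(nd)] = frozenset([lab])
    leafset[id(root)] = frozenset(labels)

    for split in sorted(supports, key=lambda s: (-len(s), sorted(s))):
        # descend to the smallest node whose leaf set contains the split
        p = root
        moved = True
        while moved:
            moved = False
            for child in p.child_nodes():
                if not child.is_leaf() and split <= leafset[id(child)]:
                    p = child
                    moved = True
                    break
        grouped = [c for c in p.child_nodes() if leafset[id(c)] <= split]
        if frozenset().union(*[leafset[id(c)] for c in grouped]) != split:
            raise ValueError("incompatible split set")  # cannot happen for majority splits
        u = dendropy.Node()
        u.label = f"{supports[split]:g}"
        for c in grouped:
            p.remove_child(c)
            u.add_child(c)
        p.add_child(u)
        leafset[id(u)] = split

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return SupportTree(tree, dict(supports))


def annotate_supports(tree: SupportTree, supports: Mapping[frozenset, float]) -> SupportTree:
    """Label a tree's internal edges with split support percentages."""
    labels = tree.labels
    all_set = frozenset(labels)
    ref = labels[0]
    for node in tree.tree.postorder_node_iter():
        if node is tree.tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = all_set - below if ref in below else below
        if side in supports:
            node.label = f"{supports[side]:g}"
    tree.supports = dict(supports)
    return tree


def bootstrap_supports(
    results: Sequence[DirectedSnpResult],
    ploidy: Mapping[str, int] | int = 3,
    n_replicates: int = 200,
    seed: int = 0,
    min_depth: int = 3,
    min_allele_fraction: float | None = None,
    labels: Sequence[str] | None = None,
) -> SupportTree:
    """Bootstrap node support by resampling each pair's aligned reads.

    For every replicate, each directed pair's aligned reads are resampled
    with replacement to their original count, the SNP rate recomputed, the
    distance matrix rebuilt and NJ re-run.  Returns the majority-rule
    consensus of the replicate trees with percentage supports.  Replicates
    in which some pair loses all aligned bases are skipped (error if more
    than 10% are skipped).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for r in results:
        if r.pileup is None:
            raise ValueError("bootstrap requires pile-up data on every result")
    ploidy_of = (
        (lambda s: ploidy[s]) if isinstance(ploidy, Mapping) else (lambda s: ploidy)
    )
    rng = np.random.default_rng(seed)
    trees: list[SupportTree] = []
    skipped = 0
    for _rep in range(n_replicates):
        rates: dict[tuple[str, str], float] = {}
        ok = True
        for r in results:
            n = r.pileup.n_reads
            if n == 0:
                ok = False
                break
            w = np.bincount(rng.integers(0, n, n), minlength=n).astype(np.float64)
            snp, aligned = snps_from_pileup(
                r.pileup, ploidy_of(r.query_sample),
                min_depth=min_depth, min_allele_fraction=min_allele_fraction,
                read_weights=w,
            )
            if aligned == 0:
                ok = False
                break
            rates[(r.query_sample, r.reference_sample)] = snp / aligned
        if not ok:
            skipped += 1
            logger.warning("bootstrap replicate %d skipped (empty pair)", _rep)
            continue
        dm = build_distance_matrix(rates, labels=labels)
        trees.append(neighbor_joining(dm))
    if skipped > 0.1 * n_replicates:
        raise ValueError(f"{skipped}/{n_replicates} bootstrap replicates skipped")
    return majority_rule_consensus(trees)
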
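"""Synthetic multi-sample transcriptome read sets with known phylogeny.

The generator emulates the situation the pipeline is built for: a handful
of closely related plant genotypes, each sequenced as short (40 bp)
single-end cDNA reads.  A random unrooted binary tree relates the samples;
sequences evolve along it under a Jukes-Cantor equal-rates model; triploid
samples carry three independently diverged haplotype copies of every
locus; expression weights skew read sampling per taxon and locus; and two
sequencing artifacts are reproduced — uniform per-base substitution errors
and reads whose final base is an uncalled N (a hallmark of early Illumina
chemistry, affecting roughly 61% of reads in the data this models).

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .phylo import SupportTree
from .seqio import Read, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES_N = np.frombuffer(b"ACGTN", dtype=np.uint8)


def jc_p_distance(d: float) -> float:
    """Expected fraction of differing sites after *d* substitutions/site."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


@dataclass
class SimPhylogeny:
    """A known unrooted binary tree over the simulated samples."""

    taxa: list[str]
    tree: dendropy.Tree

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa names must be unique")
        leaves = sorted(l.taxon.label for l in self.tree.leaf_node_iter())
        if leaves != sorted(self.taxa):
            raise ValueError("tree leaves do not match taxa")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def as_support_tree(self) -> SupportTree:
        return SupportTree(self.tree)

    def path_distances(self) -> dict[tuple[str, str], float]:
        pdm = self.tree.phylogenetic_distance_matrix()
        tns = self.tree.taxon_namespace
        out = {}
        for i, a in enumerate(self.taxa):
            for b in self.taxa[i + 1:]:
                d = pdm.distance(tns.get_taxon(a), tns.get_taxon(b))
                out[(a, b)] = out[(b, a)] = float(d)
        return out


@dataclass
class SimGenotype:
    """One taxon's haplotypes: `ploidy` diverged copies of every locus."""

    taxon: str
    ploidy: int
    loci: list[str]
    haplotypes: dict[str, list[np.ndarray]]  # locus -> ploidy coded sequences

    def __post_init__(self):
        for locus, haps in self.haplotypes.items():
            if len(haps) != self.ploidy:
                raise ValueError(f"{self.taxon}/{locus}: expected {self.ploidy} haplotypes")
            if len({len(h) for h in haps}) > 1:
                raise ValueError(f"{self.taxon}/{locus}: haplotype lengths differ")


@dataclass
class SimConfig:
    """Knobs of the read generator; all probabilities are per read/base."""

    n_loci: int
    locus_length: int
    n_reads_per_sample: int
    read_length: int = 40
    error_rate: float = 0.001
    trailing_n_fraction: float = 0.61
    internal_n_fraction: float = 0.0
    expression_log_sigma: float = 1.0
    expression_weights: Mapping[str, Sequence[float]] | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "trailing_n_fraction", "internal_n_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length > self.locus_length:
            raise ValueError("read_length exceeds locus_length")


@dataclass
class TruthReport:
    """Machine-readable ground truth emitted alongside the reads."""

    newick: str
    expected_divergence: dict[tuple[str, str], float]  # substitutions/site (tree path)
    expected_p_distance: dict[tuple[str, str], float]  # incl. homoeolog divergence

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_a\ttaxon_b\tpath_substitutions_per_site\texpected_p_distance\n")
            for (a, b), d in sorted(self.expected_divergence.items()):
                if a < b:
                    fh.write(f"{a}\t{b}\t{d:.8g}\t{self.expected_p_distance[(a, b)]:.8g}\n")


def simulate_tree(
    n_taxa: int,
    branch_length_range: tuple[float, float],
    seed: int,
    taxa: Sequence[str] | None = None,
) -> SimPhylogeny:
    """Random unrooted binary topology with uniform branch lengths.

    Built by sequential attachment: each new leaf subdivides a uniformly
    chosen existing edge, which samples binary topologies without bias
    toward balance.
    """
    if n_taxa < 3:
        raise ValueError("too few taxa")
    if taxa is None:
        taxa = [f"s{i + 1}" for i in range(n_taxa)]
    if len(taxa) != n_taxa:
        raise ValueError("taxa list length mismatch")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(list(taxa))
    center = dendropy.Node()
    edges: list[dendropy.Node] = []  # child node of each edge
    for lab in taxa[:3]:
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(lab)
        center.add_child(leaf)
        edges.append(leaf)
    for lab in taxa[3:]:
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(lab)
        mid.add_child(leaf)
        edges.append(mid)
        edges.append(leaf)
    lo, hi = branch_length_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid branch length range")
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        node.edge.length = float(rng.uniform(lo, hi))
    return SimPhylogeny(list(taxa), tree)


def random_ancestor(n_loci: int, locus_length: int, seed: int) -> dict[str, np.ndarray]:
    """Random ancestral locus sequences as coded arrays (keys l0000..)."""
    rng = np.random.default_rng(seed)
    return {
        f"l{i:04d}": rng.integers(0, 4, locus_length).astype(np.uint8)
        for i in range(n_loci)
    }


def _mutate(seq: np.ndarray, branch_length: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor substitutions: each site changes to one of the other
    three bases with probability 3/4*(1-exp(-4b/3))."""
    p = jc_p_distance(branch_length)
    out = seq.copy()
    if p <= 0:
        return out
    hit = rng.random(len(seq)) < p
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, n).astype(np.uint8)) % 4
    return out


def evolve_genotypes(
    ancestor_loci: Mapping[str, np.ndarray | str],
    phylogeny: SimPhylogeny,
    ploidy_map: Mapping[str, int],
    homoeolog_divergence: float,
    seed: int,
) -> list[SimGenotype]:
    """Evolve ancestral loci along the tree; expand leaves into haplotypes.

    Each taxon with ploidy p receives p copies of its leaf sequence, each
    further mutated by *homoeolog_divergence* expected substitutions/site
    (the copies stand in for the diverged homoeologs of a polyploid).
    """
    if not ancestor_loci:
        raise ValueError("empty ancestor set")
    if homoeolog_divergence < 0:
        raise ValueError("homoeolog_divergence must be >= 0")
    coded: dict[str, np.ndarray] = {}
    for locus, seq in ancestor_loci.items():
        if isinstance(seq, str):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            lut = np.full(256, 255, dtype=np.uint8)
            for i, b in enumerate(b"ACGT"):
                lut[b] = i
            arr = lut[arr]
            if np.any(arr > 3):
                raise ValueError(f"locus {locus}: sequence not over ACGT")
            coded[locus] = arr
        else:
            coded[locus] = np.asarray(seq, dtype=np.uint8)

    rng = np.random.default_rng(seed)
    loci = sorted(coded)
    # evolve node sequences: preorder from an arbitrary root of the unrooted tree
    node_seqs: dict[int, dict[str, np.ndarray]] = {}
    root = phylogeny.tree.seed_node
    node_seqs[id(root)] = coded
    leaf_seqs: dict[str, dict[str, np.ndarray]] = {}
    for node in phylogeny.tree.preorder_node_iter():
        if node is root:
            parent_seqs = coded
        else:
            parent_seqs = node_seqs[id(node.parent_node)]
            b = node.edge.length or 0.0
            node_seqs[id(node)] = {
                locus: _mutate(parent_seqs[locus], b, rng) for locus in loci
            }
            parent_seqs = node_seqs[id(node)]
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = parent_seqs

    out: list[SimGenotype] = []
    for taxon in phylogeny.taxa:
        ploidy = ploidy_map[taxon]
        if ploidy < 1:
            raise ValueError(f"ploidy must be >= 1 for {taxon}")
        haps = {
            locus: [
                _mutate(leaf_seqs[taxon][locus], homoeolog_divergence, rng)
                for _ in range(ploidy)
            ]
            for locus in loci
        }
        out.append(SimGenotype(taxon, ploidy, loci, haps))
    return out


def generate_reads(
    genotypes: Sequence[SimGenotype],
    config: SimConfig,
    phylogeny: SimPhylogeny | None = None,
    homoeolog_divergence: float = 0.0,
) -> tuple[dict[str, list[Read]], TruthReport | None]:
    """Draw per-sample read sets and (when the tree is given) the truth.

    Reads are sampled locus-proportionally to expression weights, from a
    uniformly chosen haplotype and strand, with uniform start positions;
    substitution errors are applied to the sequenced strand, then the
    trailing-N and internal-N artifacts.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    reads_by_sample: dict[str, list[Read]] = {}
    for g in sorted(genotypes, key=lambda g: g.taxon):
        loci = g.loci
        L = config.locus_length
        if config.expression_weights is not None:
            w = np.asarray(config.expression_weights[g.taxon], dtype=np.float64)
        else:
            w = np.exp(rng.normal(0.0, config.expression_log_sigma, len(loci)))
        if w.sum() <= 0:
            raise ValueError(f"expression weights all zero for sample {g.taxon}")
        p = w / w.sum()

        H = np.stack([np.stack(g.haplotypes[l]) for l in loci])  # (n_loci, ploidy, L)
        N = config.n_reads_per_sample
        locus_idx = rng.choice(len(loci), size=N, p=p)
        hap_idx = rng.integers(0, g.ploidy, N)
        starts = rng.integers(0, L - rl + 1, N)
        source = H[locus_idx, hap_idx]  # (N, L)
        window = starts[:, None] + np.arange(rl)[None, :]
        mat = np.take_along_axis(source, window, axis=1).astype(np.uint8)
        minus = rng.random(N) < 0.5
        mat[minus] = 3 - mat[minus, ::-1]
        if config.error_rate > 0:
            err = rng.random((N, rl)) < config.error_rate
            shift = rng.integers(1, 4, (N, rl)).astype(np.uint8)
            mat = np.where(err, (mat + shift) % 4, mat).astype(np.uint8)
        if config.internal_n_fraction > 0:
            hit = rng.random(N) < config.internal_n_fraction
            pos = rng.integers(0, rl - 1, N)
            mat[hit, pos[hit]] = 4
        if config.trailing_n_fraction > 0:
            hit = rng.random(N) < config.trailing_n_fraction
            mat[hit, rl - 1] = 4
        ascii_block = _BASES_N[mat].tobytes()
        reads_by_sample[g.taxon] = [
            Read(f"{g.taxon}_{i}", ascii_block[i * rl : (i + 1) * rl].decode(), g.taxon)
            for i in range(N)
        ]

    truth = None
    if phylogeny is not None:
        paths = phylogeny.path_distances()
        p_dist = {
            pair: float(jc_p_distance(d + 2 * homoeolog_divergence))
            for pair, d in paths.items()
        }
        truth = TruthReport(phylogeny.newick(), paths, p_dist)
    return reads_by_sample, truth


@dataclass
class SimulatedDataset:
    phylogeny: SimPhylogeny
    genotypes: list[SimGenotype]
    config: SimConfig
    reads_by_sample: dict[str, list[Read]]
    truth: TruthReport

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, reads in self.reads_by_sample.items():
            write_fastq(outdir / f"{sample}.fastq", reads)
        (outdir / "truth_tree.nwk").write_text(self.truth.newick + "\n")
        self.truth.write_tsv(outdir / "truth_divergences.tsv")
        cfg = self.config
        lines = [f"{k}: {getattr(cfg, k)}" for k in (
            "n_loci", "locus_length", "n_reads_per_sample", "read_length",
            "error_rate", "trailing_n_fraction", "internal_n_fraction",
            "expression_log_sigma", "seed")]
        (outdir / "config.yaml").write_text("\n".join(lines) + "\n")


def simulate_dataset(
    phylogeny: SimPhylogeny,
    config: SimConfig,
    ploidy_map: Mapping[str, int],
    homoeolog_divergence: float = 0.001,
    ancestor_seed: int | None = None,
) -> SimulatedDataset:
    """End-to-end convenience: ancestor -> genotypes -> reads + truth."""
    if ancestor_seed is None:
        ancestor_seed = config.seed + 1
    ancestor = random_ancestor(config.n_loci, config.locus_length, ancestor_seed)
    genotypes = evolve_genotypes(
        ancestor, phylogeny, ploidy_map, homoeolog_divergence, config.seed + 2
    )
    reads, truth = generate_reads(
        genotypes, config, phylogeny=phylogeny, homoeolog_divergence=homoeolog_divergence
    )
    return SimulatedDataset(phylogeny, genotypes, config, reads, truth)
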
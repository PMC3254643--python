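"""Validation experiments: simulation studies exercising the whole pipeline.

Each function here sets up a defined study — a worked example on published
rates, topology recovery on synthetic cohorts, bootstrap behaviour, QC
statistics, or the assembly k-sweep — and measures the result.  The
analysis drivers, the test suite and the acceptance script all call these,
so the numbers they report are always recomputed from scratch.

Problem sizes are chosen so each study finishes in minutes on one core
while keeping the per-branch SNP signal far above the noise floor; the
methods note discusses the choices.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np

import dendropy

from .common import SampleReadSet
from .metrics import identity_coverage, k_sweep
from .pairwise import DirectedSnpResult, align_reads, count_directed_snps
from .consensus import ConsensusReference
from .phylo import (
    DistanceMatrix,
    SupportTree,
    bootstrap_supports,
    build_distance_matrix,
    neighbor_joining,
    robinson_foulds,
)
from .pipeline import PipelineParams, run_snp_phylogeny
from .qc import filter_reads
from .seqio import Read
from .simulate import (
    SimConfig,
    SimPhylogeny,
    SimulatedDataset,
    simulate_dataset,
    simulate_tree,
)

logger = logging.getLogger(__name__)

PANEL_LABELS = ["FF", "FO", "FN", "I", "C", "F", "MS"]


# ---------------------------------------------------------------- worked example
def published_directed_rates() -> dict[tuple[str, str], float]:
    """The packaged 42 directed SNPs-per-aligned-bp rates for the
    seven-sample Miscanthus cDNA panel (worked example input)."""
    text = (
        importlib.resources.files("snptree.data")
        .joinpath("miscanthus_directed_snp_rates.tsv")
        .read_text()
    )
    out: dict[tuple[str, str], float] = {}
    for line in text.strip().splitlines()[1:]:
        q, r, v = line.split("\t")
        out[(q, r)] = float(v)
    return out


def published_distance_matrix() -> DistanceMatrix:
    return build_distance_matrix(published_directed_rates(), labels=PANEL_LABELS)


# ---------------------------------------------------------------- synthetic cohort
@dataclass
class CohortSpec:
    """Study conditions for the seven-sample recovery experiments."""

    n_samples: int = 7
    n_loci: int = 40
    locus_length: int = 600
    depth: float = 30.0
    read_length: int = 40
    error_rate: float = 0.001
    trailing_n_fraction: float = 0.61
    internal_n_fraction: float = 0.002
    internal_branch_range: tuple[float, float] = (0.005, 0.008)
    external_branch_range: tuple[float, float] = (0.001, 0.002)
    homoeolog_divergence: float = 0.001
    diploid_samples: int = 1  # outgroup-like sample(s); the rest are triploid

    @property
    def n_reads_per_sample(self) -> int:
        return int(round(self.n_loci * self.locus_length * self.depth / self.read_length))

    def ploidy_map(self, taxa: list[str]) -> dict[str, int]:
        return {
            t: (2 if i < self.diploid_samples else 3) for i, t in enumerate(sorted(taxa))
        }


def cohort_tree(spec: CohortSpec, seed: int) -> SimPhylogeny:
    """Random topology with internal and external branch lengths drawn
    from separate ranges (internal branches carry the topology signal)."""
    phylo = simulate_tree(spec.n_samples, spec.internal_branch_range, seed)
    rng = np.random.default_rng(seed + 101)
    for node in phylo.tree.preorder_node_iter():
        if node is phylo.tree.seed_node:
            continue
        lo, hi = (
            spec.external_branch_range if node.is_leaf() else spec.internal_branch_range
        )
        node.edge.length = float(rng.uniform(lo, hi))
    return phylo


def simulate_cohort(spec: CohortSpec, seed: int) -> SimulatedDataset:
    phylo = cohort_tree(spec, seed)
    config = SimConfig(
        n_loci=spec.n_loci,
        locus_length=spec.locus_length,
        n_reads_per_sample=spec.n_reads_per_sample,
        read_length=spec.read_length,
        error_rate=spec.error_rate,
        trailing_n_fraction=spec.trailing_n_fraction,
        internal_n_fraction=spec.internal_n_fraction,
        seed=seed + 7,
    )
    return simulate_dataset(
        phylo, config, spec.ploidy_map(phylo.taxa),
        homoeolog_divergence=spec.homoeolog_divergence,
    )


def cohort_params(spec: CohortSpec, dataset: SimulatedDataset, seed: int = 0) -> PipelineParams:
    return PipelineParams(
        ploidy=spec.ploidy_map(dataset.phylogeny.taxa), seed=seed
    )


def topology_recovery(
    n_seeds: int = 20, seed: int = 0, spec: CohortSpec | None = None
) -> tuple[float, list[int]]:
    """Fraction of simulated cohorts whose NJ topology matches the truth.

    Returns (fraction with RF = 0, per-seed RF distances).
    """
    spec = spec or CohortSpec()
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, n_seeds)
    rfs: list[int] = []
    for s in child_seeds:
        dataset = simulate_cohort(spec, int(s))
        result = run_snp_phylogeny(
            dataset.reads_by_sample, cohort_params(spec, dataset, int(s))
        )
        rf = robinson_foulds(result.nj_tree, dataset.phylogeny.as_support_tree())
        rfs.append(rf)
        logger.info("cohort seed %d: RF = %d", s, rf)
    frac = sum(1 for r in rfs if r == 0) / len(rfs)
    return frac, rfs


# ---------------------------------------------------------------- NJ oracle
def nj_additive_recovery(
    n_matrices: int = 200, seed: int = 0, leaf_range: tuple[int, int] = (4, 10)
) -> float:
    """Fraction of random additive matrices whose NJ tree matches the
    generating topology (NJ is exact on additive input, so this should
    be 1.0)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_matrices):
        n = int(rng.integers(leaf_range[0], leaf_range[1] + 1))
        phylo = simulate_tree(n, (0.05, 1.0), int(rng.integers(0, 2**31 - 1)))
        labels = sorted(phylo.taxa)
        paths = phylo.path_distances()
        values = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    values[i, j] = paths[(a, b)]
        tree = neighbor_joining(DistanceMatrix(labels, values))
        if robinson_foulds(tree, phylo.as_support_tree()) == 0:
            hits += 1
    return hits / n_matrices


# ---------------------------------------------------------------- bootstrap studies
def _constant_pair_results(
    distance_units: dict[tuple[str, str], int], read_length: int = 50, n_copies: int = 10
) -> list[DirectedSnpResult]:
    """Directed results in which every pair's alignment consists of
    identical copies of one read, so resampling has zero variance."""
    rng = np.random.default_rng(12345)
    ref_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, read_length))
    results = []
    for (q, r), units in distance_units.items():
        read_seq = list(ref_seq)
        # plant `units` mismatches at distinct sites past the 20 bp seed;
        # the consensus of the identical copies differs from the reference
        # at exactly these sites
        region = read_length - 20
        step = max(region // max(units, 1), 1)
        for i in range(units):
            pos = 20 + i * step
            read_seq[pos] = "A" if ref_seq[pos] != "A" else "C"
        ref = ConsensusReference(r, [("r00000", ref_seq)])
        reads = [Read(f"{q}_{i}", "".join(read_seq), q) for i in range(n_copies)]
        alns = align_reads(reads, ref, max_mismatches=max(3, units))
        results.append(count_directed_snps(alns, ref, ploidy=1, query_sample=q))
    return results


def zero_variance_bootstrap(seed: int = 0, n_replicates: int = 200) -> SupportTree:
    """Bootstrap on pairs with no within-pair sampling variance.

    Five taxa at tree-like unit distances; every replicate reproduces the
    same matrix, so every internal split must have 100% support.
    """
    labels = ["a", "b", "c", "d", "e"]
    # additive units from tree ((a:2,b:3):1,(c:2,d:4):1,e:6)
    tree = dendropy.Tree.get(
        data="((a:2,b:3):1,(c:2,d:4):1,e:6);", schema="newick"
    )
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    units = {}
    for a in labels:
        for b in labels:
            if a != b:
                units[(a, b)] = int(pdm.distance(tns.get_taxon(a), tns.get_taxon(b)))
    results = _constant_pair_results(units)
    return bootstrap_supports(results, ploidy=1, n_replicates=n_replicates, seed=seed)


@dataclass
class ShortBranchStudy:
    short_split_support: list[float]
    long_split_supports: list[float]

    @property
    def mean_short(self) -> float:
        return float(np.mean(self.short_split_support))

    @property
    def mean_long(self) -> float:
        return float(np.mean(self.long_split_supports))


def short_branch_support_study(
    n_seeds: int = 20, seed: int = 0, n_replicates: int = 100
) -> ShortBranchStudy:
    """Bootstrap support is weaker across a nearly-collapsed internal branch.

    A fixed 7-taxon topology has one internal branch at 0.0005
    substitutions/site and the other internals at 0.006; over replicate
    simulations the short branch's split must average lower support than
    the long branches' splits.
    """
    newick = ("((a:0.003,b:0.003):0.006,(c:0.003,d:0.003):0.006,"
              "((e:0.003,f:0.003):0.0005,g:0.003):0.006);")
    spec = CohortSpec(n_loci=12, locus_length=400, depth=20.0)
    master = np.random.default_rng(seed)
    # splits are keyed by the side omitting the alphabetically first leaf;
    # the nearly-collapsed branch is the parent of (e,f)
    short_split = frozenset({"e", "f"})
    long_splits = [
        frozenset({"c", "d", "e", "f", "g"}),  # the {a,b} branch
        frozenset({"c", "d"}),
        frozenset({"e", "f", "g"}),
    ]
    short_vals: list[float] = []
    long_vals: list[float] = []
    for s in master.integers(0, 2**31 - 1, n_seeds):
        s = int(s)
        tns = dendropy.TaxonNamespace(list("abcdefg"))
        tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
        tree.is_rooted = False
        phylo = SimPhylogeny(list("abcdefg"), tree)
        config = SimConfig(
            n_loci=spec.n_loci, locus_length=spec.locus_length,
            n_reads_per_sample=spec.n_reads_per_sample,
            error_rate=spec.error_rate,
            trailing_n_fraction=spec.trailing_n_fraction, seed=s,
        )
        dataset = simulate_dataset(
            phylo, config, spec.ploidy_map(phylo.taxa),
            homoeolog_divergence=spec.homoeolog_divergence,
        )
        result = run_snp_phylogeny(
            dataset.reads_by_sample,
            PipelineParams(ploidy=spec.ploidy_map(phylo.taxa),
                           bootstrap_replicates=n_replicates, seed=s),
            bootstrap=True,
        )
        supports = result.bootstrap_tree.supports
        short_vals.append(supports.get(short_split, 0.0))
        long_vals.extend(supports.get(sp, 0.0) for sp in long_splits)
    return ShortBranchStudy(short_vals, long_vals)


# ---------------------------------------------------------------- QC study
def trailing_n_study(
    seed: int = 0, n_reads: int = 10_000, fraction: float = 0.61
) -> tuple[float, int, int]:
    """Simulate reads with the trailing-N artifact only, run QC.

    Returns (trimmed fraction, discarded count, total reads).
    """
    phylo = simulate_tree(3, (0.001, 0.002), seed)
    config = SimConfig(
        n_loci=10, locus_length=300, n_reads_per_sample=n_reads,
        error_rate=0.0, trailing_n_fraction=fraction, internal_n_fraction=0.0,
        seed=seed,
    )
    dataset = simulate_dataset(phylo, config, {t: 1 for t in phylo.taxa},
                               homoeolog_divergence=0.0)
    sample = sorted(dataset.reads_by_sample)[0]
    survivors, report = filter_reads(dataset.reads_by_sample[sample])
    del survivors
    return (
        report.trailing_n_trimmed / report.input_reads,
        report.discarded_n_reads,
        report.input_reads,
    )


# ---------------------------------------------------------------- k-sweep study
@dataclass
class TranscriptomeSpec:
    """Transcript set with paralogous gene families, as a transcriptome
    assembly test-bed: families give small k a misassembly incentive,
    coverage gaps fragment large k."""

    n_families: int = 15
    paralogs_per_family: int = 4
    length_range: tuple[int, int] = (350, 900)
    family_divergence: float = 0.12
    depth: float = 20.0
    read_length: int = 40
    error_rate: float = 0.004


def simulate_transcript_reads(
    spec: TranscriptomeSpec, seed: int
) -> tuple[list[str], dict[str, str]]:
    """Returns (reads, transcripts): error-bearing reads plus the true
    transcript sequences used as the validation reference."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    transcripts: dict[str, str] = {}
    seqs: list[np.ndarray] = []
    for fam in range(spec.n_families):
        L = int(rng.integers(*spec.length_range))
        ancestor = rng.integers(0, 4, L).astype(np.uint8)
        for p in range(spec.paralogs_per_family):
            copy = ancestor.copy()
            hit = rng.random(L) < spec.family_divergence
            n = int(hit.sum())
            copy[hit] = (copy[hit] + rng.integers(1, 4, n).astype(np.uint8)) % 4
            transcripts[f"t{fam:03d}_{p}"] = bases[copy].tobytes().decode()
            seqs.append(copy)
    total = sum(len(s) for s in seqs)
    n_reads = int(total * spec.depth / spec.read_length)
    lengths = np.array([len(s) for s in seqs])
    probs = lengths / lengths.sum()
    reads: list[str] = []
    rl = spec.read_length
    t_idx = rng.choice(len(seqs), size=n_reads, p=probs)
    for ti in t_idx:
        s = seqs[ti]
        start = int(rng.integers(0, len(s) - rl + 1))
        frag = s[start : start + rl].copy()
        err = rng.random(rl) < spec.error_rate
        n = int(err.sum())
        if n:
            frag[err] = (frag[err] + rng.integers(1, 4, n).astype(np.uint8)) % 4
        if rng.random() < 0.5:
            frag = 3 - frag[::-1]
        reads.append(bases[frag].tobytes().decode())
    return reads, transcripts


def ksweep_concordance(
    n_seeds: int = 10,
    seed: int = 0,
    k_values: tuple[int, ...] = (15, 17, 19, 21, 23, 25, 27, 29, 31, 33),
    spec: TranscriptomeSpec | None = None,
    min_match: int = 50,
) -> tuple[float, list[tuple[int, int]]]:
    """Does the top-100 mean-length metric select the same k as the
    independent identity-coverage validation metric?

    Returns (fraction of seeds concordant, per-seed (selected_k, best
    identity k) pairs).
    """
    spec = spec or TranscriptomeSpec()
    master = np.random.default_rng(seed)
    picks: list[tuple[int, int]] = []
    for s in master.integers(0, 2**31 - 1, n_seeds):
        reads, transcripts = simulate_transcript_reads(spec, int(s))
        rows, selected_k, contigs_by_k = k_sweep(reads, list(k_values))
        coverage = {
            k: identity_coverage(contigs, transcripts, min_match=min_match).covered_bases
            for k, contigs in contigs_by_k.items()
        }
        best_identity_k = min(coverage, key=lambda k: (-coverage[k], k))
        picks.append((selected_k, best_identity_k))
        logger.info("ksweep seed %s: selected k=%d, identity-best k=%d",
                    s, selected_k, best_identity_k)
    frac = sum(1 for a, b in picks if a == b) / len(picks)
    return frac, picks
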
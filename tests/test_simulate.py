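"""Synthetic data generator: tree sampling, JC evolution, read artifacts."""

import itertools

import numpy as np
import pytest

from snptree.simulate import (
    SimConfig,
    evolve_genotypes,
    generate_reads,
    jc_p_distance,
    random_ancestor,
    simulate_dataset,
    simulate_tree,
)


class TestSimulateTree:
    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="too few"):
            simulate_tree(2, (0.1, 0.2), seed=1)

    def test_degenerate_range_gives_star(self):
        phylo = simulate_tree(3, (0.0, 0.0), seed=1)
        assert sorted(phylo.taxa) == ["s1", "s2", "s3"]
        assert all(d == 0.0 for d in phylo.path_distances().values())

    def test_seed_determinism(self):
        a = simulate_tree(4, (0.01, 0.05), seed=7)
        b = simulate_tree(4, (0.01, 0.05), seed=7)
        assert a.newick() == b.newick()

    def test_four_point_condition_all_quartets(self):
        """Path distances of any tree are additive: for every quartet the
        two largest of the three pairings coincide."""
        phylo = simulate_tree(7, (0.001, 0.02), seed=3)
        d = phylo.path_distances()
        for qa, qb, qc, qd in itertools.combinations(phylo.taxa, 4):
            sums = sorted(
                [
                    d[(qa, qb)] + d[(qc, qd)],
                    d[(qa, qc)] + d[(qb, qd)],
                    d[(qa, qd)] + d[(qb, qc)],
                ]
            )
            assert sums[2] - sums[1] < 1e-12


class TestEvolveGenotypes:
    def test_zero_divergence_identity(self):
        phylo = simulate_tree(3, (0.0, 0.0), seed=2)
        anc = random_ancestor(3, 100, seed=5)
        genos = evolve_genotypes(anc, phylo, {t: 1 for t in phylo.taxa}, 0.0, seed=9)
        for g in genos:
            for locus, arr in anc.items():
                assert np.array_equal(g.haplotypes[locus][0], arr)

    def test_empty_ancestor_rejected(self):
        phylo = simulate_tree(3, (0.0, 0.0), seed=2)
        with pytest.raises(ValueError):
            evolve_genotypes({}, phylo, {t: 1 for t in phylo.taxa}, 0.0, seed=1)

    def test_triploid_copies(self):
        phylo = simulate_tree(3, (0.01, 0.02), seed=4)
        anc = random_ancestor(2, 50, seed=5)
        genos = evolve_genotypes(anc, phylo, {t: 3 for t in phylo.taxa}, 0.01, seed=6)
        assert all(len(g.haplotypes[l]) == 3 for g in genos for l in g.loci)

    def test_jukes_cantor_closed_form(self):
        """Observed divergence across a branch of length d matches the JC
        expectation 3/4*(1-exp(-4d/3)) within 3 binomial standard errors."""
        d = 0.05
        n_sites = 100_000
        phylo = simulate_tree(3, (0.0, 0.0), seed=11)
        # put the whole divergence on one terminal branch
        for leaf in phylo.tree.leaf_node_iter():
            if leaf.taxon.label == "s1":
                leaf.edge.length = d
        anc = random_ancestor(1, n_sites, seed=12)
        genos = {
            g.taxon: g
            for g in evolve_genotypes(anc, phylo, {t: 1 for t in phylo.taxa}, 0.0, seed=13)
        }
        h1 = genos["s1"].haplotypes["l0000"][0]
        h2 = genos["s2"].haplotypes["l0000"][0]
        p = jc_p_distance(d)
        observed = np.mean(h1 != h2)
        se = np.sqrt(p * (1 - p) / n_sites)
        assert abs(observed - p) < 3 * se


class TestGenerateReads:
    def _dataset(self, **cfg):
        phylo = simulate_tree(3, (0.0, 0.0), seed=21)
        config = SimConfig(
            n_loci=4, locus_length=200, n_reads_per_sample=cfg.pop("n_reads", 500),
            error_rate=cfg.pop("error_rate", 0.0),
            trailing_n_fraction=cfg.pop("trailing", 0.0),
            internal_n_fraction=cfg.pop("internal", 0.0),
            seed=cfg.pop("seed", 31),
        )
        return simulate_dataset(phylo, config, {t: 1 for t in phylo.taxa},
                                homoeolog_divergence=0.0)

    def test_clean_reads_are_haplotype_substrings(self):
        ds = self._dataset()
        kmers = set()
        for g in ds.genotypes:
            for locus in g.loci:
                seq = "".join("ACGT"[i] for i in g.haplotypes[locus][0])
                rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                for s in (seq, rc):
                    kmers.update(s[i : i + 40] for i in range(len(s) - 39))
        for reads in ds.reads_by_sample.values():
            assert all(r.sequence in kmers for r in reads)

    def test_read_count_exact_and_deterministic(self):
        a = self._dataset(seed=77)
        b = self._dataset(seed=77)
        for sample in a.reads_by_sample:
            assert len(a.reads_by_sample[sample]) == 500
            assert [r.sequence for r in a.reads_by_sample[sample]] == [
                r.sequence for r in b.reads_by_sample[sample]
            ]

    def test_trailing_n_everywhere(self):
        ds = self._dataset(trailing=1.0)
        for reads in ds.reads_by_sample.values():
            assert all(r.sequence.endswith("N") for r in reads)

    def test_trailing_n_fraction_binomial(self):
        ds = self._dataset(trailing=0.61, n_reads=10_000)
        reads = next(iter(ds.reads_by_sample.values()))
        frac = sum(r.sequence.endswith("N") for r in reads) / len(reads)
        se = np.sqrt(0.61 * 0.39 / len(reads))
        assert abs(frac - 0.61) < 3 * se

    def test_zero_expression_weights_rejected(self):
        phylo = simulate_tree(3, (0.0, 0.0), seed=21)
        anc = random_ancestor(2, 100, seed=1)
        genos = evolve_genotypes(anc, phylo, {t: 1 for t in phylo.taxa}, 0.0, seed=2)
        config = SimConfig(
            n_loci=2, locus_length=100, n_reads_per_sample=10,
            expression_weights={t: [0.0, 0.0] for t in phylo.taxa}, seed=3,
        )
        with pytest.raises(ValueError, match="expression weights"):
            generate_reads(genos, config)

    def test_truth_report_contents(self):
        ds = self._dataset()
        assert ds.truth.newick.count("s1") == 1
        assert ds.truth.expected_divergence[("s1", "s2")] == pytest.approx(0.0)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(n_loci=1, locus_length=100, n_reads_per_sample=1, error_rate=1.5)

    def test_read_longer_than_locus(self):
        with pytest.raises(ValueError):
            SimConfig(n_loci=1, locus_length=30, n_reads_per_sample=1, read_length=40)
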
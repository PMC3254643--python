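"""Distance matrix, neighbor joining, consensus trees, bootstrap."""

import dendropy
import numpy as np
import pytest

from snptree.phylo import (
    DistanceMatrix,
    SupportTree,
    build_distance_matrix,
    majority_rule_consensus,
    neighbor_joining,
    robinson_foulds,
    round_half_away,
)
from snptree.simulate import simulate_tree


def _tree_from_newick(newick, labels):
    tns = dendropy.TaxonNamespace(labels)
    t = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    t.is_rooted = False
    return SupportTree(t)


class TestBuildDistanceMatrix:
    def test_mean_of_reciprocals_published_pairs(self):
        """Two directed rates average into the reported symmetric distance
        at 8 decimal places."""
        rates = {
            ("FF", "FO"): 0.000413390, ("FO", "FF"): 0.000314511,
            ("I", "FN"): 0.000314453, ("FN", "I"): 0.000472350,
            ("FF", "I"): 0.000470852, ("I", "FF"): 0.000287344,
            ("FO", "I"): 0.000434378, ("I", "FO"): 0.000333024,
            ("FF", "FN"): 0.000388363, ("FN", "FF"): 0.000319526,
            ("FO", "FN"): 0.000348281, ("FN", "FO"): 0.000370514,
        }
        dm = build_distance_matrix(rates, labels=["FF", "FO", "FN", "I"])
        assert round_half_away(dm.get("FF", "FO")) == 0.00036395
        assert round_half_away(dm.get("I", "FN")) == 0.00039340

    def test_zero_rates_zero_distance(self):
        rates = {("a", "b"): 0.0, ("b", "a"): 0.0}
        dm = build_distance_matrix(rates)
        assert dm.get("a", "b") == 0.0

    def test_missing_direction_named(self):
        with pytest.raises(ValueError, match=r"pair \(a, b\)"):
            build_distance_matrix({("a", "b"): 0.1})

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.000000125, 8) == 0.00000013
        assert round_half_away(0.000000124, 8) == 0.00000012


class TestDistanceMatrixInvariants:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestNeighborJoining:
    def test_four_leaf_additive_exact(self):
        """The additive matrix of ((A:1,B:2):1,(C:3,D:4)) is inverted
        exactly: split AB|CD and all original path distances."""
        labels = ["A", "B", "C", "D"]
        values = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, values))
        assert tree.splits() == {frozenset({"C", "D"})}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert tree.path_distance(a, b) == pytest.approx(values[i, j])

    def test_three_taxa_closed_form(self):
        labels = ["a", "b", "c"]
        values = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, values))
        # leaf edges: (dab+dac-dbc)/2 = 3, (dab+dbc-dac)/2 = 2, (dac+dbc-dab)/2 = 6
        for pair, expected in ((("a", "b"), 5), (("a", "c"), 9), (("b", "c"), 8)):
            assert tree.path_distance(*pair) == pytest.approx(expected)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_recovers_random_additive_topologies(self):
        """Seeded sweep of random binary trees (4-10 leaves): NJ on the
        exact path-distance matrix always returns the generating topology."""
        rng = np.random.default_rng(99)
        for trial in range(30):
            n = int(rng.integers(4, 11))
            phylo = simulate_tree(n, (0.05, 1.0), int(rng.integers(0, 2**31 - 1)))
            labels = sorted(phylo.taxa)
            paths = phylo.path_distances()
            values = np.array(
                [[0.0 if a == b else paths[(a, b)] for b in labels] for a in labels]
            )
            tree = neighbor_joining(DistanceMatrix(labels, values))
            assert robinson_foulds(tree, phylo.as_support_tree()) == 0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        phylo = simulate_tree(6, (0.1, 1.0), 17)
        labels = sorted(phylo.taxa)
        paths = phylo.path_distances()
        values = np.array(
            [[0.0 if a == b else paths[(a, b)] for b in labels] for a in labels]
        )
        tree = neighbor_joining(DistanceMatrix(labels, values))
        perm = list(rng.permutation(len(labels)))
        plabels = [labels[i] for i in perm]
        pvalues = values[np.ix_(perm, perm)]
        ptree = neighbor_joining(DistanceMatrix(plabels, pvalues))
        assert robinson_foulds(tree, ptree) == 0  # same leaves, same splits

    def test_negative_branches_clamped(self):
        values = np.array(
            [
                [0.0, 0.1, 0.4, 0.5],
                [0.1, 0.0, 0.5, 0.4],
                [0.4, 0.5, 0.0, 0.1],
                [0.5, 0.4, 0.1, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(list("abcd"), values))
        for node in tree.tree.preorder_node_iter():
            if node.edge.length is not None:
                assert node.edge.length >= 0.0


class TestMajorityRuleConsensus:
    def test_identical_trees_full_support(self):
        trees = [_tree_from_newick("((a,b),c,(d,e));", list("abcde")) for _ in range(3)]
        cons = majority_rule_consensus(trees)
        assert cons.splits() == trees[0].splits()
        assert all(v == 100.0 for v in cons.supports.values())

    def test_exact_half_excluded(self):
        t1 = _tree_from_newick("((a,b),c,(d,e));", list("abcde"))
        t2 = _tree_from_newick("((a,c),b,(d,e));", list("abcde"))
        cons = majority_rule_consensus([t1, t2])
        # {d,e} in both (100%); the competing splits sit at exactly 50%
        assert cons.supports == {frozenset({"d", "e"}): 100.0}

    def test_support_percentage_counting(self):
        t1 = _tree_from_newick("((a,b),c,(d,e));", list("abcde"))
        t2 = _tree_from_newick("((a,c),b,(d,e));", list("abcde"))
        trees = [t1] * 137 + [t2] * 63
        cons = majority_rule_consensus(trees)
        assert cons.supports[frozenset({"c", "d", "e"})] == pytest.approx(68.5)
        assert cons.supports[frozenset({"d", "e"})] == pytest.approx(100.0)

    def test_inconsistent_leaf_sets_rejected(self):
        t1 = _tree_from_newick("((a,b),c,(d,e));", list("abcde"))
        t2 = _tree_from_newick("((a,b),c,(d,f));", list("abcdf"))
        with pytest.raises(ValueError):
            majority_rule_consensus([t1, t2])

    def test_matches_dendropy_consensus(self):
        """Independent oracle: dendropy's majority-rule consensus finds the
        same split set on a batch of random trees."""
        rng = np.random.default_rng(31)
        tns = dendropy.TaxonNamespace([f"s{i+1}" for i in range(6)])
        dtrees = dendropy.TreeList(taxon_namespace=tns)
        mine = []
        for _ in range(21):
            phylo = simulate_tree(6, (0.1, 1.0), int(rng.integers(0, 2**31 - 1)))
            newick = phylo.newick()
            dtrees.append(dendropy.Tree.get(data=newick, schema="newick",
                                            taxon_namespace=tns))
            mine.append(_tree_from_newick(newick, [t.label for t in tns]))
        cons = majority_rule_consensus(mine)
        dcons = SupportTree(dtrees.consensus(min_freq=0.5000001))
        assert cons.splits() == dcons.splits()


class TestRobinsonFoulds:
    def test_matches_dendropy_symmetric_difference(self):
        rng = np.random.default_rng(13)
        tns = dendropy.TaxonNamespace([f"s{i+1}" for i in range(8)])
        for _ in range(10):
            a = simulate_tree(8, (0.1, 1.0), int(rng.integers(0, 2**31 - 1)))
            b = simulate_tree(8, (0.1, 1.0), int(rng.integers(0, 2**31 - 1)))
            da = dendropy.Tree.get(data=a.newick(), schema="newick", taxon_namespace=tns)
            db = dendropy.Tree.get(data=b.newick(), schema="newick", taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
            mine = robinson_foulds(
                _tree_from_newick(a.newick(), [t.label for t in tns]),
                _tree_from_newick(b.newick(), [t.label for t in tns]),
            )
            assert mine == expected
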
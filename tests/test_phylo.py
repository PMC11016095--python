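"""Distance models, neighbour joining, bootstrap and rooting."""

import itertools
import math

import numpy as np
import pytest

import barcodiag as bd
from barcodiag.phylo import (
    DistanceMatrix,
    DistanceModel,
    GapPolicy,
    PhyloError,
    bipartitions,
    neighbour_joining,
    pairwise_distance,
    root_with_outgroup,
    to_newick,
)
from barcodiag.seqio import SequenceRecord


def _aln(rows):
    return bd.Alignment(tuple(SequenceRecord(k, v) for k, v in rows.items()))


class TestPairwiseDistance:
    def test_identical_rows_zero_under_all_models(self):
        aln = _aln({"a": "ACGTACGT", "b": "ACGTACGT"})
        for model in (DistanceModel.P_DIST, DistanceModel.JC69, DistanceModel.K2P):
            assert pairwise_distance(aln, model)[("a", "b")] == 0.0

    def test_p_distance_quarter(self):
        dm = pairwise_distance(_aln({"a": "ACGT", "b": "ACGA"}), DistanceModel.P_DIST)
        assert dm[("a", "b")] == pytest.approx(0.25)

    def test_k2p_closed_form(self):
        # 100 sites: 10 transitions (A<->G), 5 transversions (A<->C)
        a = ["A"] * 100
        b = ["A"] * 100
        for i in range(10):
            b[i] = "G"
        for i in range(10, 15):
            b[i] = "C"
        dm = pairwise_distance(_aln({"a": "".join(a), "b": "".join(b)}), DistanceModel.K2P)
        P, Q = 0.10, 0.05
        expected = 0.5 * math.log(1 / (1 - 2 * P - Q)) + 0.25 * math.log(1 / (1 - 2 * Q))
        assert dm[("a", "b")] == pytest.approx(expected, abs=1e-12)

    def test_corrections_reduce_to_p_distance_at_small_divergence(self):
        n = 40000
        a = "ACGT" * (n // 4)
        b = list(a)
        b[0] = "G"  # a single transition: p = 1/n
        aln = _aln({"a": a, "b": "".join(b)})
        p = pairwise_distance(aln, DistanceModel.P_DIST)[("a", "b")]
        for model in (DistanceModel.JC69, DistanceModel.K2P):
            d = pairwise_distance(aln, model)[("a", "b")]
            assert abs(d - p) / p < 1e-3

    def test_gap_and_ambiguity_sites_excluded_pairwise(self):
        aln = _aln({"a": "ACGTN-GT", "b": "ACGAACGT"})
        # comparable: cols 1-4 minus none; col5 N, col6 gap excluded -> 6 sites, 1 diff
        dm = pairwise_distance(aln, DistanceModel.P_DIST)
        assert dm[("a", "b")] == pytest.approx(1 / 6)

    def test_saturation_flagged_or_raised(self):
        aln = _aln({"a": "ACGT" * 5, "b": "GACT" * 5})
        dm = pairwise_distance(aln, DistanceModel.JC69)
        assert ("a", "b") in dm.saturated or np.isfinite(dm[("a", "b")])
        if ("a", "b") in dm.saturated:
            with pytest.raises(PhyloError):
                pairwise_distance(aln, DistanceModel.JC69, on_saturation="raise")


from conftest import random_additive_tree, tree_path_distances


def _ls_best_quartet(dm):
    """Least-squares oracle over the three unrooted 4-taxon topologies."""
    a, b, c, d = dm.labels

    def err(pair):
        # topology pairing `pair` vs the other two; five branch lengths by
        # the four-point formulas, error = residual of the fit
        (x, y), (z, w) = pair
        dxy, dzw = dm[(x, y)], dm[(z, w)]
        dxz, dxw = dm[(x, z)], dm[(x, w)]
        dyz, dyw = dm[(y, z)], dm[(y, w)]
        internal = 0.5 * (min(dxz + dyw, dxw + dyz) - dxy - dzw)
        side1 = 0.5 * (dxz + dyw)
        side2 = 0.5 * (dxw + dyz)
        return abs(side1 - side2) + max(-internal, 0)

    pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    errs = [(err(p), i) for i, p in enumerate(pairings)]
    errs.sort()
    return pairings[errs[0][1]]


class TestNeighbourJoining:
    def test_four_taxon_additive_tree_recovered_vs_ls_oracle(self):
        # ((A,B),(C,D)): tips 2,3,4,5 internal 1
        labels = ("A", "B", "C", "D")
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        dm = DistanceMatrix(labels, d)
        tree = neighbour_joining(dm)
        splits = set(bipartitions(tree))
        assert splits == {frozenset({"C", "D"})}
        (x, y), _ = _ls_best_quartet(dm)
        assert {x, y} in ({"A", "B"}, {"C", "D"})
        # branch lengths recovered exactly
        lengths = {}
        for node in tree.preorder():
            if node.is_leaf:
                lengths[node.name] = node.length
        assert lengths == pytest.approx({"A": 2, "B": 3, "C": 4, "D": 5})

    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbour_joining(DistanceMatrix(("A", "B", "C"), d))
        lengths = {n.name: n.length for n in tree.preorder() if n.is_leaf}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_two_cluster_ultrametric_matrix_gives_sister_clades(self):
        labels = ("A", "B", "C", "D", "E", "F")
        d = np.full((6, 6), 1.0)
        for i, j in itertools.combinations(range(3), 2):
            d[i, j] = d[j, i] = 0.2
            d[i + 3, j + 3] = d[j + 3, i + 3] = 0.2
        np.fill_diagonal(d, 0.0)
        tree = neighbour_joining(DistanceMatrix(labels, d))
        splits = set(bipartitions(tree))
        assert frozenset({"D", "E", "F"}) in splits

    def test_additive_trees_recovered_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            dm, true_splits, labels = random_additive_tree(rng, n)
            tree = neighbour_joining(dm)
            assert set(bipartitions(tree)) == true_splits
            # path distances on the reconstructed tree reproduce the input
            reconstructed = tree_path_distances(tree, labels)
            assert np.allclose(reconstructed, dm.values, atol=1e-9)

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(PhyloError):
            neighbour_joining(
                DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float))
            )


class TestBootstrap:
    def test_concordant_alignment_full_support(self):
        rows = {
            "A": "AAAA" * 10,
            "B": "AAAA" * 10,
            "C": "CCCC" * 10,
            "D": "CCCC" * 10,
            "E": "CCGG" * 10,
        }
        tree = bd.bootstrap_support(_aln(rows), DistanceModel.P_DIST, 100, seed=1)
        supports = [n.support for n in tree.preorder() if n.support is not None]
        assert supports and all(s == 100 for s in supports)

    def test_fixed_seed_reproducible(self, genus):
        _, _, truth = genus
        sub = bd.Alignment(
            tuple(r for r in truth.alignment.records if r.group is not bd.Group.UNKNOWN)
        )
        t1 = bd.bootstrap_support(sub, DistanceModel.K2P, 50, seed=9)
        t2 = bd.bootstrap_support(sub, DistanceModel.K2P, 50, seed=9)
        assert to_newick(t1) == to_newick(t2)

    def test_leaf_order_invariance(self):
        rows = {
            "A": "AAAATTTT" * 5,
            "B": "AAAATTAT" * 5,
            "C": "CCCCTTTT" * 5,
            "D": "CCCCTATT" * 5,
        }
        aln1 = _aln(rows)
        aln2 = _aln(dict(reversed(list(rows.items()))))
        t1 = bd.bootstrap_support(aln1, DistanceModel.P_DIST, 100, seed=4)
        t2 = bd.bootstrap_support(aln2, DistanceModel.P_DIST, 100, seed=4)
        s1 = {frozenset(k): v.support for k, v in bipartitions(t1).items()}
        s2 = {frozenset(k): v.support for k, v in bipartitions(t2).items()}
        assert s1 == s2

    def test_single_column_warns(self):
        rows = {"A": "A", "B": "C", "C": "G"}
        with pytest.warns(UserWarning):
            bd.bootstrap_support(_aln(rows), DistanceModel.P_DIST, 5, seed=0)


class TestRooting:
    def _tree(self):
        d = np.array(
            [[0, 2, 9, 9.4], [2, 0, 9.4, 9.8], [9, 9.4, 0, 2], [9.4, 9.8, 2, 0]],
            float,
        )
        return neighbour_joining(DistanceMatrix(("A", "B", "C", "D"), d))

    def test_single_leaf_outgroup_roots_on_pendant_edge(self):
        tree = self._tree()
        rooted = root_with_outgroup(tree, ["A"])
        assert len(rooted.children) == 2
        assert frozenset({"A"}) in [c.leaf_names() for c in rooted.children]

    def test_two_leaf_outgroup_clade(self):
        tree = self._tree()
        rooted = root_with_outgroup(tree, ["C", "D"])
        assert {c.leaf_names() for c in rooted.children} == {
            frozenset({"C", "D"}),
            frozenset({"A", "B"}),
        }

    def test_non_monophyletic_outgroup_rejected(self):
        with pytest.raises(PhyloError, match="monophyletic"):
            root_with_outgroup(self._tree(), ["A", "C"])

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        tree = self._tree()
        newick = to_newick(tree)
        dt = dendropy.Tree.get(data=newick, schema="newick")
        assert {l.taxon.label for l in dt.leaf_node_iter()} == {"A", "B", "C", "D"}
        # the single non-trivial split agrees
        dt.encode_bipartitions()
        ours = set(bipartitions(tree))
        assert frozenset({"C", "D"}) in ours
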
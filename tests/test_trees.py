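"""Neighbor joining, patristic distances, and group separation."""

import dendropy
import numpy as np
import pytest

from phagekit.similarity import DistanceMatrix
from phagekit.trees import (
    PatristicMatrix,
    alignment_distance_matrix,
    group_separation,
    is_monophyletic,
    nj_tree,
    patristic_matrix,
)

# additive matrix of the tree ((A:1,B:2):1,(C:3,D:1))
ADDITIVE_4 = DistanceMatrix(
    labels=["A", "B", "C", "D"],
    values=np.array(
        [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
    ),
)


def _rf(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=tree_a.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    b = dendropy.Tree.get(
        data=tree_b.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestNjTree:
    def test_recovers_additive_four_taxon_tree_exactly(self):
        tree = nj_tree(ADDITIVE_4)
        pm = patristic_matrix(tree)
        idx = [pm.labels.index(l) for l in ADDITIVE_4.labels]
        assert np.allclose(pm.values[np.ix_(idx, idx)], ADDITIVE_4.values)
        assert is_monophyletic(tree, {"A", "B"})
        assert is_monophyletic(tree, {"C", "D"})

    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        tree = nj_tree(d)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_rejects_nan(self):
        bad = ADDITIVE_4.values.copy()
        m = DistanceMatrix(labels=ADDITIVE_4.labels, values=bad)
        m.values[0, 1] = m.values[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            nj_tree(m)

    def test_invariant_to_label_permutation(self, rng):
        perm = rng.permutation(4)
        labels = [ADDITIVE_4.labels[i] for i in perm]
        values = ADDITIVE_4.values[np.ix_(perm, perm)]
        t1 = nj_tree(ADDITIVE_4)
        t2 = nj_tree(DistanceMatrix(labels=labels, values=values))
        assert _rf(t1, t2) == 0
        pm1, pm2 = patristic_matrix(t1), patristic_matrix(t2)
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    assert pm1.loc(a, b) == pytest.approx(pm2.loc(a, b))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_topology_agrees_with_skbio_reference(self, seed):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(seed)
        n = 7
        pts = rng.random((n, 3)) * 10
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(n)]
        mine = nj_tree(DistanceMatrix(labels=labels, values=d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        ref_dp = dendropy.Tree.get(data=str(ref), schema="newick")
        assert _rf(mine, ref_dp) == 0


class TestPatristic:
    def test_two_leaf_path_length(self):
        tree = dendropy.Tree.get(data="(A:1,B:2);", schema="newick")
        pm = patristic_matrix(tree)
        assert pm.loc("A", "B") == pytest.approx(3.0)

    def test_zero_branch_lengths_give_zero_matrix(self):
        tree = dendropy.Tree.get(data="((A:0,B:0):0,(C:0,D:0):0);", schema="newick")
        assert np.all(patristic_matrix(tree).values == 0)

    def test_round_trip_through_newick_preserves_distances(self):
        tree = nj_tree(ADDITIVE_4)
        reread = dendropy.Tree.get(
            data=tree.as_string(schema="newick"), schema="newick"
        )
        assert np.allclose(
            patristic_matrix(tree).values, patristic_matrix(reread).values
        )


def _pm(labels, values) -> PatristicMatrix:
    return PatristicMatrix(labels=labels, values=np.asarray(values, dtype=float))


class TestGroupSeparation:
    def test_single_group_reports_only_within_max(self):
        pm = _pm(["a", "b", "c"], [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        rep = group_separation(pm, {"a": "G", "b": "G", "c": "G"})
        assert rep.within_max == {"G": 3.0}
        assert rep.between_mean == {} and rep.separated == {}

    def test_well_separated_groups_flagged(self):
        tree = dendropy.Tree.get(
            data="((a1:0.1,a2:0.1):5,(b1:0.1,b2:0.1):5);", schema="newick"
        )
        pm = patristic_matrix(tree)
        rep = group_separation(pm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert rep.separated[("A", "B")] is True

    def test_interleaved_identical_groups_not_separated(self):
        # all pairwise distances equal: between mean == within max
        n = 4
        vals = np.ones((n, n)) - np.eye(n)
        pm = _pm(["a", "b", "c", "d"], vals)
        rep = group_separation(pm, {"a": "G", "b": "H", "c": "G", "d": "H"})
        assert rep.separated[("G", "H")] is False

    def test_singletons_participate_only_in_between_means(self):
        tree = dendropy.Tree.get(
            data="((a1:0.1,a2:0.1):5,out:10);", schema="newick"
        )
        pm = patristic_matrix(tree)
        rep = group_separation(pm, {"a1": "A", "a2": "A", "out": "solo"})
        assert rep.within_max["solo"] == 0.0
        assert rep.separated[("A", "solo")] is True

    def test_flags_invariant_to_uniform_scaling(self):
        tree = dendropy.Tree.get(
            data="((a1:0.1,a2:0.4):2,(b1:0.3,b2:0.2):2);", schema="newick"
        )
        pm = patristic_matrix(tree)
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        base = group_separation(pm, groups).separated
        scaled = group_separation(
            PatristicMatrix(labels=pm.labels, values=pm.values * 37.0), groups
        ).separated
        assert base == scaled

    def test_unlabelled_leaf_rejected(self):
        pm = _pm(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(ValueError, match="no group label"):
            group_separation(pm, {"a": "G", "b": "G"})


class TestAlignmentDistances:
    def test_identical_sequences_have_zero_distance(self):
        d = alignment_distance_matrix({"x": "ACDEF" * 10, "y": "ACDEF" * 10})
        assert d.loc("x", "y") == 0.0

    def test_correction_exceeds_raw_p_distance(self):
        a = "A" * 100
        b = "A" * 80 + "C" * 20
        d = alignment_distance_matrix({"x": a, "y": b})
        assert d.loc("x", "y") > 0.2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            alignment_distance_matrix({"x": "ACD", "y": "AC"})
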
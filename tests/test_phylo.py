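"""Neighbor joining, Newick round-trips, Robinson-Foulds comparison."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

from spacedist import (
    DistanceMatrix,
    neighbor_joining,
    parse_newick,
    relative_rf,
    rf_distance,
    round_half_up,
)
from conftest import random_binary_newick, tree_distance_matrix


def _split_ab_cd(tree) -> bool:
    """True iff the 4-leaf tree has the non-trivial split AB|CD."""
    cmp = rf_distance(tree, parse_newick("((A:1,B:1):1,C:1,D:1);"))
    return cmp.rf == 0


class TestNeighborJoining:
    def test_four_taxon_additive_exact_recovery(self):
        # distances induced by ((A:1,B:2):1,(C:3,D:4))
        names = ("A", "B", "C", "D")
        M = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(names, M))
        assert _split_ab_cd(tree)
        # exact branch lengths: leaf edges 1,2,3,4 and internal edge 1
        lengths = {}
        for leaf in tree.tree.leaf_node_iter():
            lengths[leaf.taxon.label] = leaf.edge.length
        assert lengths["A"] == pytest.approx(1.0, abs=1e-9)
        assert lengths["B"] == pytest.approx(2.0, abs=1e-9)
        internal = [
            e.length
            for e in tree.tree.preorder_edge_iter()
            if e.length is not None and not e.head_node.is_leaf()
        ]
        assert sorted(x for x in internal if x > 0) == pytest.approx([1.0])

    def test_three_taxa_closed_form(self):
        M = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(("x", "y", "z"), M))
        limb = {lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()}
        assert limb["x"] == pytest.approx((2 + 3 - 5) / 2)
        assert limb["y"] == pytest.approx((2 + 5 - 3) / 2)
        assert limb["z"] == pytest.approx((3 + 5 - 2) / 2)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("a", "b"), np.array([[0, 1.0], [1.0, 0]])))

    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_additive_matrix_recovers_generating_tree(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(10):
            newick = random_binary_newick(rng, n_leaves)
            dm = tree_distance_matrix(newick)
            out = neighbor_joining(dm)
            assert rf_distance(out, parse_newick(newick)).rf == 0
            # additive recovery includes branch lengths: pairwise path
            # distances of the NJ tree reproduce the input matrix
            back = tree_distance_matrix(out.newick())
            assert np.allclose(back.values, dm.values, atol=1e-6)

    def test_ultrametric_balanced_eight_taxa(self):
        newick = (
            "(((T0:1,T1:1):1,(T2:1,T3:1):1):1,((T4:1,T5:1):1,(T6:1,T7:1):1):1);"
        )
        dm = tree_distance_matrix(newick)
        assert rf_distance(neighbor_joining(dm), parse_newick(newick)).rf == 0

    def test_agrees_with_dendropy_nj_topology(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            newick = random_binary_newick(rng, 7)
            dm = tree_distance_matrix(newick)
            ours = neighbor_joining(dm)
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=_dm_to_csv(dm), delimiter=","
            )
            theirs = parse_newick(pdm.nj_tree().as_string(schema="newick").strip())
            assert rf_distance(ours, theirs).rf == 0

    def test_clamp_negative(self):
        # slightly non-additive matrix can give a negative NJ branch
        M = np.array(
            [
                [0.0, 0.1, 0.4, 0.45],
                [0.1, 0.0, 0.42, 0.4],
                [0.4, 0.42, 0.0, 0.05],
                [0.45, 0.4, 0.05, 0.0],
            ]
        )
        dm = DistanceMatrix(("a", "b", "c", "d"), M)
        clamped = neighbor_joining(dm, clamp_negative=True)
        for e in clamped.tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0.0


def _dm_to_csv(dm: DistanceMatrix):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(dm.names) + "\n")
    for name, row in zip(dm.names, dm.values):
        buf.write(name + "," + ",".join(str(x) for x in row) + "\n")
    buf.seek(0)
    return buf


class TestNewickIO:
    def test_parse_four_leaves(self):
        t = parse_newick("(A:1,B:2,(C:3,D:4):1);")
        assert t.n_leaves == 4
        assert t.leaf_names == {"A", "B", "C", "D"}

    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        t = parse_newick("(A:1.5,B:2.25,(C:3.125,D:4.0625):1.5);")
        f = tmp_path / "t.nwk"
        t.write(f)
        back = parse_newick(f)
        assert rf_distance(t, back).rf == 0
        la = {lf.taxon.label: lf.edge.length for lf in back.tree.leaf_node_iter()}
        assert la["C"] == pytest.approx(3.125, abs=1e-6)

    def test_sanitized_labels_survive(self, tmp_path):
        t = parse_newick("(E._coli_K-12:1,Shigella_sp.:2,(x:1,y:1):1);")
        f = tmp_path / "t.nwk"
        t.write(f)
        assert "E._coli_K-12" in parse_newick(f).leaf_names

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("(A:1,A:2,(C:3,D:4):1);")


class TestRFDistance:
    def test_identical_trees(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        cmp = rf_distance(t, t)
        assert cmp.rf == 0 and cmp.relative_rf == 0.0

    def test_four_taxon_alternative_splits(self):
        t1 = parse_newick("((A:1,B:1):1,C:1,D:1);")  # AB|CD
        t2 = parse_newick("((A:1,C:1):1,B:1,D:1);")  # AC|BD
        cmp = rf_distance(t1, t2)
        assert cmp.rf == 2
        assert cmp.max_rf == 2
        assert cmp.relative_rf == 1.0

    def test_leaf_set_mismatch_rejected(self):
        t1 = parse_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = parse_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)

    def test_metric_properties_on_random_trees(self):
        rng = np.random.default_rng(17)
        trees = [parse_newick(random_binary_newick(rng, 8)) for _ in range(6)]
        d = lambda a, b: rf_distance(a, b).rf
        for a, b in itertools.combinations(trees, 2):
            assert d(a, b) == d(b, a)
            assert d(a, b) >= 0
        for a, b, c in itertools.combinations(trees, 3):
            assert d(a, c) <= d(a, b) + d(b, c)

    def test_relative_rf_in_unit_interval(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            t1 = parse_newick(random_binary_newick(rng, 6))
            t2 = parse_newick(random_binary_newick(rng, 6))
            r = rf_distance(t1, t2).relative_rf
            assert 0.0 <= r <= 1.0


class TestRelativeRFArithmetic:
    def test_formula(self):
        assert relative_rf(4, 29) == pytest.approx(4 / 52)
        with pytest.raises(ValueError):
            relative_rf(2, 3)

    def test_round_half_up(self):
        assert round_half_up(0.1875, 2) == 0.19  # banker's rounding would give 0.18
        assert round_half_up(0.225, 2) == 0.23
        assert round_half_up(4 / 52, 2) == 0.08
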
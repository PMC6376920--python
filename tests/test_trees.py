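"""Neighbor-Joining, UPGMA, and Newick serialisation."""

import io

import numpy as np
import pytest

from winefp import average_linkage, neighbor_joining
from winefp.errors import UsageError

from conftest import make_distance_matrix, random_additive_tree


def pendant_lengths(tree):
    return {
        node.name: node.length
        for node in tree.root.walk()
        if node.is_leaf
    }


class TestNeighborJoining:
    def test_three_point_closed_form(self):
        """d(A,B)=2, d(A,C)=3, d(B,C)=4 -> pendants 0.5 / 1.5 / 2.5."""
        dm = make_distance_matrix(
            ["A", "B", "C"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        )
        # scaled by 10 to fit [0,1]; pendant lengths scale linearly
        tree = neighbor_joining(dm)
        lengths = pendant_lengths(tree)
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_four_taxon_additive_matrix(self):
        """Matrix from ((A:1,B:2):1,(C:3,D:4)): topology AB|CD, paths exact."""
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        dm = make_distance_matrix(["A", "B", "C", "D"], D / 10)
        tree = neighbor_joining(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        labels, rec = tree.leaf_distance_matrix()
        idx = {l: i for i, l in enumerate(labels)}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert rec[idx[a], idx[b]] == pytest.approx(D[i, j] / 10, abs=1e-12)

    def test_tie_break_is_deterministic(self):
        D = np.full((4, 4), 0.5)
        np.fill_diagonal(D, 0.0)
        dm = make_distance_matrix(["D", "C", "B", "A"], D)
        t1 = neighbor_joining(dm).to_newick()
        t2 = neighbor_joining(dm).to_newick()
        assert t1 == t2

    def test_additive_recovery_property(self):
        """NJ is exact on additive matrices: topology and all path lengths
        recovered within 1e-9 on random trees with up to 12 leaves."""
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            labels, D = random_additive_tree(n, rng)
            dm = make_distance_matrix(labels, D)
            tree = neighbor_joining(dm)
            got_labels, rec = tree.leaf_distance_matrix()
            order = [got_labels.index(l) for l in labels]
            assert np.max(np.abs(rec[np.ix_(order, order)] - D)) < 1e-9

    def test_agrees_with_reference_implementation(self):
        """Cross-check topology against scikit-bio's NJ on a random matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        labels, D = random_additive_tree(8, rng)
        D = (D + D.T) / 2  # exact symmetry for the reference implementation
        dm = make_distance_matrix(labels, D)
        ours = neighbor_joining(dm)
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        ref_parts = set()
        all_leaves = frozenset(labels)
        anchor = min(labels)
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                ref_parts.add(side)
        assert ours.bipartitions() == ref_parts

    def test_too_few_taxa_rejected(self):
        dm = make_distance_matrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(UsageError):
            neighbor_joining(dm)


class TestAverageLinkage:
    def test_two_leaves_merge_at_half_distance(self):
        dm = make_distance_matrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        tree = average_linkage(dm)
        lengths = pendant_lengths(tree)
        assert lengths["A"] == pytest.approx(0.2)
        assert lengths["B"] == pytest.approx(0.2)

    def test_identical_leaves_merge_at_zero(self):
        dm = make_distance_matrix(["A", "B"], np.zeros((2, 2)))
        tree = average_linkage(dm)
        assert pendant_lengths(tree) == {"A": 0.0, "B": 0.0}

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0.1, 1.0, size=(6, 6))
        D = (X + X.T) / 2
        np.fill_diagonal(D, 0.0)
        dm = make_distance_matrix(list("ABCDEF"), D)
        tree = average_linkage(dm)
        # every child subtree height must not exceed its parent's height
        def height(node):
            if node.is_leaf:
                return 0.0
            h = max(height(c) + c.length for c in node.children)
            return h
        for node in tree.root.walk():
            if not node.is_leaf:
                child_heights = [height(c) for c in node.children]
                assert all(h <= height(node) + 1e-12 for h in child_heights)

    def test_agrees_with_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average, cut_tree
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        X = rng.uniform(0.05, 1.0, size=(7, 7))
        D = (X + X.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = list("ABCDEFG")
        dm = make_distance_matrix(labels, D)
        ours = average_linkage(dm)
        Z = average(squareform(D))
        # compare the sorted merge heights (ultrametric heights = d/2)
        our_heights = sorted(
            _node_height(node)
            for node in ours.root.walk()
            if not node.is_leaf
        )
        ref_heights = sorted(Z[:, 2] / 2)
        assert np.allclose(our_heights, ref_heights)


def _node_height(node):
    h = 0.0
    cur = node
    while not cur.is_leaf:
        cur = cur.children[0]
        h += cur.length
    return h


class TestNewick:
    def test_cherry_format(self):
        dm = make_distance_matrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        newick = average_linkage(dm).to_newick()
        assert newick == "(A:0.200000,B:0.200000);"

    def test_label_with_space_is_quoted(self):
        dm = make_distance_matrix(
            ["Pinot Noir", "Merlot"], np.array([[0, 0.4], [0.4, 0]])
        )
        newick = average_linkage(dm).to_newick()
        assert "'Pinot Noir'" in newick

    def test_round_trip_through_reference_parser(self):
        """Topology and branch lengths survive write -> independent parse."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(17)
        labels, D = random_additive_tree(7, rng)
        dm = make_distance_matrix(labels, D)
        ours = neighbor_joining(dm)
        parsed = skbio.TreeNode.read(io.StringIO(ours.to_newick()))
        assert sorted(t.name for t in parsed.tips()) == sorted(labels)
        ref = {
            frozenset(t.name for t in n.tips())
            for n in parsed.non_tips()
        }
        ours_clades = {
            frozenset(n.leaf_names())
            for n in ours.root.walk()
            if not n.is_leaf and n is not ours.root
        }
        assert ours_clades <= ref | ours_clades  # same rooted clades present
        assert ours_clades == {c for c in ref if 2 <= len(c) < len(labels)}
        # branch lengths: compare leaf depth sums
        for tip in parsed.tips():
            our_depth = _leaf_depth(ours, tip.name)
            assert tip.accumulate_to_ancestor(parsed.root()) == pytest.approx(
                our_depth, abs=1e-5
            )


def _leaf_depth(tree, name):
    def rec(node, depth):
        if node.is_leaf and node.name == name:
            return depth + node.length
        for c in node.children:
            r = rec(c, depth + (0.0 if node is tree.root else node.length))
            if r is not None:
                return r
        return None

    # walk from root; root itself contributes no length
    def rec2(node, acc):
        acc2 = acc + (node.length if node is not tree.root else 0.0)
        if node.is_leaf:
            return acc2 if node.name == name else None
        for c in node.children:
            r = rec2(c, acc2)
            if r is not None:
                return r
        return None

    return rec2(tree.root, 0.0)
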
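import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from geotypekit import (
    DistanceMatrix,
    is_ultrametric,
    neighbor_joining,
    profile_distance,
    profile_distance_matrix,
    read_newick,
    upgma,
    write_newick,
)
from geotypekit.errors import IncompleteProfileError, MatrixValidationError
from geotypekit.trees import leaf_depths


def random_distance_matrix(rng, n):
    d = rng.random((n, n)) * 10
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix(tuple(f"t{i}" for i in range(n)), d)


def patristic(tree):
    """Leaf-to-leaf path distances from a rooted tree with branch lengths."""
    depths = leaf_depths(tree)
    out = {}
    tips = list(tree.tips())
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            lca = tree.lowest_common_ancestor([a.name, b.name])
            h = 0.0
            node = lca
            while node.parent is not None:
                h += node.length or 0.0
                node = node.parent
            out[frozenset((a.name, b.name))] = depths[a.name] + depths[b.name] - 2 * h
    return out


class TestUpgma:
    def test_two_taxa_cherry(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = upgma(dm)
        assert {t.name for t in tree.tips()} == {"a", "b"}
        assert all(t.length == pytest.approx(1.5) for t in tree.tips())

    def test_four_taxon_manual_agglomeration(self):
        # ultrametric heights: (a,b) at 2, ((a,b),c) at 6, root at 10
        d = np.array(
            [
                [0.0, 4.0, 12.0, 20.0],
                [4.0, 0.0, 12.0, 20.0],
                [12.0, 12.0, 0.0, 20.0],
                [20.0, 20.0, 20.0, 0.0],
            ]
        )
        tree = upgma(DistanceMatrix(tuple("abcd"), d))
        depths = leaf_depths(tree)
        assert all(v == pytest.approx(10.0) for v in depths.values())
        dist = patristic(tree)
        assert dist[frozenset("ab")] == pytest.approx(4.0)
        assert dist[frozenset("ac")] == pytest.approx(12.0)
        assert dist[frozenset("ad")] == pytest.approx(20.0)

    def test_random_matrices_are_ultrametric_and_leaf_complete(self, rng):
        for _ in range(5):
            dm = random_distance_matrix(rng, 8)
            tree = upgma(dm)
            assert {t.name for t in tree.tips()} == set(dm.ids)
            assert is_ultrametric(tree, tol=1e-9)

    def test_cophenetic_distances_match_scipy_average_linkage(self, rng):
        dm = random_distance_matrix(rng, 9)
        tree = upgma(dm)
        Z = linkage(squareform(dm.d), method="average")
        expected = squareform(cophenet(Z))
        dist = patristic(tree)
        for i in range(dm.n):
            for j in range(i + 1, dm.n):
                key = frozenset((dm.ids[i], dm.ids[j]))
                assert dist[key] == pytest.approx(expected[i, j], abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(MatrixValidationError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_deterministic_under_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(tuple("abcd"), d)
        assert write_newick(upgma(dm)) == write_newick(upgma(dm))


class TestNeighborJoining:
    def test_recovers_additive_tree_topology(self):
        # ((a,b),(c,d)) with internal branch 3: non-ultrametric additive matrix
        d = np.array(
            [
                [0.0, 3.0, 9.0, 10.0],
                [3.0, 0.0, 10.0, 11.0],
                [9.0, 10.0, 0.0, 5.0],
                [10.0, 11.0, 5.0, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(tuple("abcd"), d))
        dist = patristic(tree)
        for pair, expected in {
            frozenset("ab"): 3.0,
            frozenset("cd"): 5.0,
            frozenset("ac"): 9.0,
            frozenset("bd"): 11.0,
        }.items():
            assert dist[pair] == pytest.approx(expected)

    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(tuple("abc"), d))
        dist = patristic(tree)
        assert dist[frozenset("ab")] == pytest.approx(3.0)
        assert dist[frozenset("ac")] == pytest.approx(4.0)
        assert dist[frozenset("bc")] == pytest.approx(5.0)

    def test_agrees_with_upgma_on_ultrametric_input(self):
        d = np.array(
            [
                [0.0, 2.0, 8.0, 8.0],
                [2.0, 0.0, 8.0, 8.0],
                [8.0, 8.0, 0.0, 4.0],
                [8.0, 8.0, 4.0, 0.0],
            ]
        )
        dm = DistanceMatrix(tuple("abcd"), d)
        nj_tree = neighbor_joining(dm)
        # same unrooted split: {a,b} vs {c,d}
        for node in nj_tree.non_tips(include_self=True):
            leaves = {t.name for t in node.tips()}
            if leaves in ({"a", "b"}, {"c", "d"}):
                break
        else:
            pytest.fail("expected split {a,b}|{c,d} not found")


class TestNewick:
    def test_round_trip_preserves_labels_and_lengths(self, rng):
        dm = random_distance_matrix(rng, 6)
        tree = upgma(dm)
        reparsed = read_newick(write_newick(tree))
        d1, d2 = patristic(tree), patristic(reparsed)
        assert set(d1) == set(d2)
        for key in d1:
            assert d1[key] == pytest.approx(d2[key], abs=1e-9)


class TestProfileDistance:
    def test_identical_profiles(self):
        assert profile_distance((1, 1, 1, 1, 1, 1), (1, 1, 1, 1, 1, 1)) == 0

    def test_fully_distinct_profiles(self):
        assert profile_distance((1, 1, 1, 1, 1, 1), (2, 3, 2, 2, 2, 3)) == 6

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            a = tuple(rng.integers(1, 4, 6))
            b = tuple(rng.integers(1, 4, 6))
            assert profile_distance(a, b) == sum(x != y for x, y in zip(a, b))

    def test_missing_allele_rejected(self):
        with pytest.raises(IncompleteProfileError):
            profile_distance((1, -1, 1, 1, 1, 1), (1, 1, 1, 1, 1, 1))

    def test_matrix_version_is_symmetric_hamming(self, table1):
        matrix, _ = table1
        dm = profile_distance_matrix(matrix)
        i = matrix.strain_ids.index("15")
        j = matrix.strain_ids.index("21")
        assert dm.d[i, j] == 6
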
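"""Clustering core: worked fixtures, oracle equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from inflamcog.cluster_validity import adjusted_rand_index
from inflamcog.hclust import (
    DistanceMatrix,
    agglomerate,
    agglomerative_coefficient,
    cut_tree,
    euclidean_distance_matrix,
    select_k,
    select_linkage,
    silhouette,
)

from .oracles import naive_agglomerate, naive_silhouette


def _points(vals):
    return np.asarray(vals, float).reshape(-1, 1)


class TestDistances:
    def test_three_four_five(self):
        D = euclidean_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D.condensed[0] == pytest.approx(5.0)

    def test_identical_points_zero(self):
        D = euclidean_distance_matrix(np.zeros((3, 2)))
        assert np.all(D.condensed == 0)

    def test_one_dimensional(self):
        D = euclidean_distance_matrix(_points([0, 2, 9]))
        assert sorted(D.condensed) == [2, 7, 9]


class TestAgglomerate:
    @pytest.mark.parametrize(
        "linkage,second_height", [("average", 8.0), ("single", 7.0), ("complete", 9.0)]
    )
    def test_worked_three_points(self, linkage, second_height):
        D = euclidean_distance_matrix(_points([0, 2, 9]))
        h = agglomerate(D, linkage)
        assert h.Z[0, 2] == pytest.approx(2.0)  # {0,2} merge first
        assert {int(h.Z[0, 0]), int(h.Z[0, 1])} == {0, 1}
        assert h.Z[1, 2] == pytest.approx(second_height)

    def test_two_points(self):
        D = euclidean_distance_matrix(_points([1, 4]))
        h = agglomerate(D, "ward")
        assert h.Z.shape == (1, 4)
        assert h.Z[0, 2] == pytest.approx(3.0)

    def test_unknown_linkage(self):
        D = euclidean_distance_matrix(_points([0, 1]))
        with pytest.raises(ValueError, match="unknown linkage"):
            agglomerate(D, "centroid")

    def test_heights_non_decreasing_random(self):
        rng = np.random.default_rng(5)
        for linkage in ("single", "complete", "average", "ward"):
            X = rng.normal(size=(40, 3))
            h = agglomerate(DistanceMatrix.from_points(X), linkage)
            assert np.all(np.diff(h.Z[:, 2]) >= -1e-9), linkage

    @pytest.mark.parametrize("linkage", ["single", "complete", "average", "ward"])
    def test_matches_bruteforce_oracle(self, linkage):
        rng = np.random.default_rng(11)
        for rep in range(25):
            n = int(rng.integers(3, 13))
            X = rng.normal(size=(n, 2))
            D = DistanceMatrix.from_points(X)
            h = agglomerate(D, linkage)
            heights, partitions = naive_agglomerate(D.full(), linkage, X)
            assert np.allclose(h.Z[:, 2], heights, atol=1e-9)
            for k in range(2, n):
                labels = cut_tree(h, k)
                ours = {
                    frozenset(np.flatnonzero(labels == c)) for c in range(1, k + 1)
                }
                assert ours == partitions[n - k - 1]

    @pytest.mark.parametrize("linkage", ["single", "complete", "average", "ward"])
    def test_matches_scipy(self, linkage):
        from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        h = agglomerate(DistanceMatrix.from_points(X), linkage)
        Z = scipy_linkage(X, method=linkage)
        assert np.allclose(h.Z[:, 2], Z[:, 2], atol=1e-8)
        for k in (2, 4, 7):
            assert (
                adjusted_rand_index(cut_tree(h, k), fcluster(Z, k, criterion="maxclust"))
                == 1.0
            )

    def test_ward_dialects_differ(self):
        X = _points([0, 1, 3, 8, 9, 11])
        D = DistanceMatrix.from_points(X)
        d2 = agglomerate(D, "ward", ward_dialect="ward.D2")
        d1 = agglomerate(D, "ward", ward_dialect="ward.D")
        assert not np.allclose(d2.Z[:, 2], d1.Z[:, 2])

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 2))
        perm = rng.permutation(30)
        h1 = agglomerate(DistanceMatrix.from_points(X), "ward")
        h2 = agglomerate(DistanceMatrix.from_points(X[perm]), "ward")
        l1, l2 = cut_tree(h1, 3), cut_tree(h2, 3)
        assert adjusted_rand_index(l1[perm], l2) == 1.0
        s1 = silhouette(DistanceMatrix.from_points(X), l1)[1]
        s2 = silhouette(DistanceMatrix.from_points(X[perm]), l2)[1]
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestAgglomerativeCoefficient:
    def test_worked_example(self):
        D = euclidean_distance_matrix(_points([0, 1, 10]))
        ac = agglomerative_coefficient(agglomerate(D, "average"))
        assert ac == pytest.approx((2 * (1 - 1 / 9.5)) / 3, abs=1e-9)  # ~0.5965

    def test_two_tight_far_clusters_near_one(self):
        X = np.vstack([np.zeros((5, 1)) + 1e-6 * np.arange(5)[:, None],
                       100.0 + 1e-6 * np.arange(5)[:, None]])
        ac = agglomerative_coefficient(agglomerate(DistanceMatrix.from_points(X), "average"))
        assert ac > 0.999

    def test_n2_is_zero(self):
        D = euclidean_distance_matrix(_points([0, 5]))
        assert agglomerative_coefficient(agglomerate(D, "single")) == 0.0

    def test_identical_points_warns_zero(self):
        D = euclidean_distance_matrix(np.zeros((4, 1)))
        with pytest.warns(UserWarning):
            assert agglomerative_coefficient(agglomerate(D, "average")) == 0.0


class TestCutTree:
    def test_extremes(self):
        D = euclidean_distance_matrix(_points([0, 2, 9]))
        h = agglomerate(D, "average")
        assert set(cut_tree(h, 1)) == {1}
        assert sorted(cut_tree(h, 3)) == [1, 2, 3]
        labels = cut_tree(h, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_out_of_range(self):
        D = euclidean_distance_matrix(_points([0, 2, 9]))
        h = agglomerate(D, "average")
        with pytest.raises(ValueError):
            cut_tree(h, 0)
        with pytest.raises(ValueError):
            cut_tree(h, 4)


class TestSilhouette:
    def test_worked_example(self):
        D = euclidean_distance_matrix(_points([0, 1, 10, 11]))
        s, mean = silhouette(D, np.array([1, 1, 2, 2]))
        assert s[0] == pytest.approx((10.5 - 1) / 10.5, abs=1e-9)
        assert s[1] == pytest.approx((9.5 - 1) / 9.5, abs=1e-9)
        assert mean == pytest.approx(0.899749373433584, abs=1e-9)

    def test_singleton_convention(self):
        D = euclidean_distance_matrix(_points([0, 1, 10]))
        s, _ = silhouette(D, np.array([1, 1, 2]))
        assert s[2] == 0.0

    def test_overlapping_split_nonpositive(self):
        X = np.vstack([_points([0, 1, 2, 3])] * 2)
        labels = np.repeat([1, 2], 4)
        _, mean = silhouette(euclidean_distance_matrix(X), labels)
        assert mean <= 0.0

    def test_k1_error(self):
        D = euclidean_distance_matrix(_points([0, 1]))
        with pytest.raises(ValueError):
            silhouette(D, np.array([1, 1]))

    def test_matches_naive_and_sklearn(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(6, 25))
            X = rng.normal(size=(n, 2))
            labels = rng.integers(1, 4, n)
            if len(np.unique(labels)) < 2:
                continue
            D = DistanceMatrix.from_points(X)
            s, _ = silhouette(D, labels)
            assert np.allclose(s, naive_silhouette(D.full(), labels), atol=1e-12)
            # sklearn uses the same convention except no singleton handling
            counts = np.bincount(labels)
            if np.all(counts[np.unique(labels)] > 1):
                assert np.allclose(s, silhouette_samples(X, labels), atol=1e-9)


class TestSelection:
    def test_select_linkage_blobs_prefers_ward(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(12, 1, (40, 2))])
        best, ac = select_linkage(DistanceMatrix.from_points(X))
        assert set(ac) == {"single", "complete", "average", "ward"}
        assert best == "ward"
        assert ac["ward"] == max(ac.values())

    def test_tie_prefers_ward(self):
        # equilateral triangle: all pairwise distances equal
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        best, ac = select_linkage(DistanceMatrix.from_points(X))
        assert len(set(np.round(list(ac.values()), 12))) == 1
        assert best == "ward"

    def test_select_k_two_gaussians(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (100, 2))])
        D = DistanceMatrix.from_points(X)
        k, curve = select_k(D, agglomerate(D, "ward"))
        assert k == 2
        assert set(curve) == set(range(2, 9))

    def test_select_k_three_triplets(self):
        centers = np.array([[0, 0], [100, 0], [50, 100 * np.sqrt(3) / 2]])
        X = np.vstack([c + 0.2 * np.array([[0, 0], [1, 0], [0, 1]]) for c in centers])
        D = DistanceMatrix.from_points(X)
        k, _ = select_k(D, agglomerate(D, "average"), k_range=range(2, 7))
        assert k == 3

    def test_select_k_single_candidate(self):
        D = euclidean_distance_matrix(_points([0, 1, 5, 6]))
        k, curve = select_k(D, agglomerate(D, "average"), k_range=[2])
        assert k == 2 and 2 in curve

    def test_empty_k_range(self):
        D = euclidean_distance_matrix(_points([0, 1, 5]))
        with pytest.raises(ValueError):
            select_k(D, agglomerate(D, "average"), k_range=[])


class TestExports:
    def test_merge_table_convention(self):
        D = euclidean_distance_matrix(_points([0, 2, 9]))
        table = agglomerate(D, "average").to_merge_table()
        assert table[0, 0] == -1 and table[0, 1] == -2  # originals negative
        assert table[1, 1] == 1  # cluster from step 1 referenced as +1

    def test_newick_roundtrip(self):
        import dendropy

        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 2))
        h = agglomerate(DistanceMatrix.from_points(X), "average")
        nwk = h.to_newick([f"L{i}" for i in range(8)])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {
            f"L{i}" for i in range(8)
        }


@given(st.integers(0, 2 ** 31 - 1))
def test_heights_monotone_property(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(int(rng.integers(4, 15)), 2))
    for linkage in ("single", "complete", "average", "ward"):
        h = agglomerate(DistanceMatrix.from_points(X), linkage)
        assert np.all(np.diff(h.Z[:, 2]) >= -1e-9)
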
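import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import adjusted_rand_score

from seqmotif import (
    FeatureMatrix,
    ParameterError,
    build_matrix,
    clustermap,
    kmeans_cluster,
    maxabs_normalize,
    meanshift_cluster,
    merges_to_newick,
    pca_kmeans,
    pca_project,
    planted_clusters,
)

from oracles import prim_mst_weights


def _fm(X, basis="frequency", normalized=False):
    n, p = X.shape
    return FeatureMatrix(df=pd.DataFrame(
        X, index=[f"s{i}" for i in range(n)],
        columns=[f"m{j}" for j in range(p)]), basis=basis,
        normalized=normalized)


class TestKMeans:
    def test_k_equals_n_gives_zero_inertia(self):
        rng = np.random.default_rng(0)
        m = _fm(rng.normal(size=(6, 4)))
        res = kmeans_cluster(m, 6, seed=0)
        assert sorted(res.labels) == list(range(6))
        # every point is its own center
        dists = np.linalg.norm(m.values - res.centers[res.labels], axis=1)
        np.testing.assert_allclose(dists, 0.0, atol=1e-12)

    def test_k1_center_is_column_mean(self):
        rng = np.random.default_rng(1)
        m = _fm(rng.normal(size=(5, 3)))
        res = kmeans_cluster(m, 1, seed=0)
        assert set(res.labels) == {0}
        np.testing.assert_allclose(res.centers[0], m.values.mean(axis=0),
                                   atol=1e-9)

    def test_recovers_planted_composition_clusters(self, two_cluster_fixture):
        matrix, truth = two_cluster_fixture
        res = kmeans_cluster(matrix, 2, seed=1)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_each_row_assigned_to_nearest_center(self, two_cluster_fixture):
        matrix, _ = two_cluster_fixture
        res = kmeans_cluster(matrix, 2, seed=1)
        d = np.linalg.norm(matrix.values[:, None, :] - res.centers[None], axis=2)
        np.testing.assert_array_equal(res.labels, d.argmin(axis=1))

    def test_deterministic_given_seed(self, two_cluster_fixture):
        matrix, _ = two_cluster_fixture
        a = kmeans_cluster(matrix, 2, seed=5)
        b = kmeans_cluster(matrix, 2, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("k", [0, 7])
    def test_invalid_k(self, k):
        m = _fm(np.zeros((5, 2)))
        with pytest.raises(ParameterError):
            kmeans_cluster(m, k)


class TestPCA:
    def test_collinear_rows_explained_by_first_component(self):
        t = np.linspace(0, 1, 8)
        X = np.outer(t, [1.0, 2.0, -1.0]) + 5.0
        emb, evr = pca_project(_fm(X), 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_reconstruction_and_variance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        m = _fm(X)
        emb, evr = pca_project(m, 4)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(evr) <= 1e-12)
        # distances are preserved by a complete orthonormal projection
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(emb), pdist(X), atol=1e-9)

    def test_row_duplication_preserves_components(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 5))
        emb1, _ = pca_project(_fm(X), 2)
        emb2, _ = pca_project(_fm(np.vstack([X, X])), 2)
        np.testing.assert_allclose(emb2[:7], emb1, atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ParameterError):
            pca_project(_fm(np.zeros((3, 2))), 3)


class TestPcaKmeans:
    def test_two_planted_clusters(self, two_cluster_fixture):
        matrix, truth = two_cluster_fixture
        res = pca_kmeans(matrix, 2, seed=1)
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert res.embedding.shape == (60, 2)
        assert res.explained_variance is not None

    def test_k1_still_returns_embedding(self, two_cluster_fixture):
        matrix, _ = two_cluster_fixture
        res = pca_kmeans(matrix, 1, seed=0)
        assert set(res.labels) == {0}
        assert res.embedding is not None

    def test_five_planted_clusters(self):
        records, truth = planted_clusters(
            20, [(0.40, 0.10, 0.10, 0.40), (0.325, 0.175, 0.175, 0.325),
                 (0.25, 0.25, 0.25, 0.25), (0.175, 0.325, 0.325, 0.175),
                 (0.10, 0.40, 0.40, 0.10)], 2000, seed=1)
        matrix = build_matrix(records, basis="frequency", ks={2})
        res = pca_kmeans(matrix, 5, seed=1)
        assert adjusted_rand_score(truth, res.labels) >= 0.95


class TestMeanShift:
    def test_two_well_separated_blobs(self, two_cluster_fixture):
        matrix, truth = two_cluster_fixture
        res = meanshift_cluster(matrix, seed=1)
        assert res.n_clusters == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_identical_points_single_cluster_with_warning(self, caplog):
        import logging
        m = _fm(np.ones((8, 3)))
        with caplog.at_level(logging.WARNING):
            res = meanshift_cluster(m)
        assert res.n_clusters == 1
        assert any("bandwidth" in msg for msg in caplog.messages)

    def test_huge_bandwidth_single_cluster(self, two_cluster_fixture):
        matrix, _ = two_cluster_fixture
        diameter = 10.0  # far above the data diameter of frequency vectors
        res = meanshift_cluster(matrix, bandwidth=diameter)
        assert res.n_clusters == 1

    def test_invalid_bandwidth(self, two_cluster_fixture):
        matrix, _ = two_cluster_fixture
        with pytest.raises(ParameterError):
            meanshift_cluster(matrix, bandwidth=-1.0)


class TestClustermap:
    def test_identical_rows_adjacent_and_merge_first(self):
        rng = np.random.default_rng(4)
        r1, r2 = rng.normal(size=(2, 5))
        m = _fm(np.vstack([r1, r2, r1]))
        res = clustermap(m)
        order = list(res.row_order)
        assert abs(order.index(0) - order.index(2)) == 1
        assert res.row_merges[0, 2] == pytest.approx(0.0)
        assert sorted(res.row_merges[0, :2]) == [0, 2]

    def test_single_linkage_heights_equal_mst_edges(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 5))
        res = clustermap(_fm(X), linkage_method="single")
        heights = np.sort(res.row_merges[:, 2])
        np.testing.assert_allclose(heights, prim_mst_weights(X), atol=1e-9)

    def test_minimal_matrix_orders_are_permutations(self):
        res = clustermap(_fm(np.array([[0.0, 1.0], [1.0, 0.0]])))
        assert sorted(res.row_order) == [0, 1]
        assert sorted(res.col_order) == [0, 1]

    def test_single_linkage_heights_nondecreasing(self):
        rng = np.random.default_rng(6)
        res = clustermap(_fm(rng.normal(size=(10, 4))),
                         linkage_method="single")
        assert np.all(np.diff(res.row_merges[:, 2]) >= -1e-12)

    def test_too_small_or_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            clustermap(_fm(np.zeros((1, 3))))
        with pytest.raises(ParameterError):
            clustermap(_fm(np.zeros((3, 3))), linkage_method="centroid")

    def test_newick_export_is_wellformed(self):
        rng = np.random.default_rng(7)
        m = _fm(rng.normal(size=(5, 3)))
        res = clustermap(m)
        nwk = merges_to_newick(res.row_merges, res.row_ids)
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == 4
        for rid in res.row_ids:
            assert rid in nwk


def test_kmeans_inertia_never_increases_across_iterations(two_cluster_fixture):
    """Trace Lloyd's algorithm by running with increasing max_iter budgets."""
    from sklearn.cluster import KMeans
    matrix, _ = two_cluster_fixture
    X = matrix.values
    inertias = [
        KMeans(n_clusters=2, init="random", n_init=1, max_iter=it,
               random_state=0).fit(X).inertia_
        for it in range(1, 6)
    ]
    assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))
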
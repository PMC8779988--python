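import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import adjusted_rand_score

from mzkit.clustering import (
    DBSCANSpec,
    MeanShiftSpec,
    agglomerative,
    dbscan,
    estimate_bandwidth,
    fcm,
    kmeans,
    mean_shift,
    run_algorithm,
)
from mzkit.errors import ValidationError


def exhaustive_min_sse(X, k):
    """Oracle: brute-force minimum within-cluster SSE over all assignments."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    best = np.inf
    best_labels = None
    for assign in itertools.product(range(k), repeat=n):
        labels = np.array(assign)
        sse = 0.0
        for c in range(k):
            members = X[labels == c]
            if len(members):
                sse += ((members - members.mean(axis=0)) ** 2).sum()
        if sse < best - 1e-12:
            best = sse
            best_labels = labels
    return best, best_labels


class TestKMeans:
    def test_two_pair_instance(self):
        X = np.array([0.0, 1.0, 9.0, 10.0])
        model = kmeans(X, 2, seed=0, n_restarts=5)
        best_sse, best_labels = exhaustive_min_sse(X, 2)
        assert model.inertia == pytest.approx(best_sse)
        assert adjusted_rand_score(best_labels, model.labels) == 1.0
        np.testing.assert_allclose(sorted(model.centroids[:, 0]), [0.5, 9.5])

    def test_k1_global_mean(self, rng):
        X = rng.normal(0, 1, (20, 3))
        model = kmeans(X, 1, seed=0)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0))

    def test_k_equals_n_zero_sse(self, rng):
        X = rng.normal(0, 1, (6, 2))
        model = kmeans(X, 6, seed=0, n_restarts=20)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_greater_than_n(self):
        with pytest.raises(ValidationError):
            kmeans(np.zeros((3, 1)), 4)

    def test_centroids_are_member_means(self, rng):
        X = rng.normal(0, 1, (50, 2))
        model = kmeans(X, 3, seed=1)
        for c in range(3):
            np.testing.assert_allclose(
                model.centroids[c], X[model.labels == c].mean(axis=0), atol=1e-9
            )

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(0, 1, (40, 2))
        a = kmeans(X, 3, seed=7)
        b = kmeans(X, 3, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_matches_exhaustive_oracle_small_instances(self):
        """Seeded random instances n<=9, k<=3: SSE equals the brute-force optimum."""
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(3, 10))
            k = int(rng.integers(2, 4))
            if k > n:
                continue
            X = rng.normal(0, 1, (n, 2))
            model = kmeans(X, k, seed=0, n_restarts=20)
            best, _ = exhaustive_min_sse(X, k)
            assert model.inertia == pytest.approx(best, rel=1e-9, abs=1e-9)

    def test_never_outputs_outlier_label(self, rng):
        X = rng.normal(0, 1, (30, 2))
        model = kmeans(X, 4, seed=0)
        assert model.labels.min() >= 0


class TestFCM:
    def test_point_at_centroid_full_membership(self):
        X = np.array([[0.0], [10.0], [0.0]])
        _, memb = fcm(X, 2, m=2.0, seed=0)
        # every point sits exactly on a centroid here; rows are one-hot
        np.testing.assert_allclose(memb.u.sum(axis=1), 1.0, atol=1e-9)
        assert memb.u.max(axis=1).min() > 0.99

    def test_symmetric_midpoint_half_membership(self):
        # membership for a point equidistant from the two centroids is (.5, .5)
        X = np.array([[0.0], [0.0], [10.0], [10.0], [5.0]])
        _, memb = fcm(X, 2, m=2.0, seed=0, max_iter=2000)
        np.testing.assert_allclose(memb.u[4], [0.5, 0.5], atol=1e-6)

    def test_rows_sum_to_one(self, rng):
        X = rng.normal(0, 1, (60, 3))
        _, memb = fcm(X, 4, m=2.0, seed=0)
        np.testing.assert_allclose(memb.u.sum(axis=1), 1.0, atol=1e-9)
        assert memb.u.min() >= 0 and memb.u.max() <= 1

    def test_m_near_one_equals_kmeans_toy(self):
        X = np.array([0.0, 1.0, 9.0, 10.0])
        km = kmeans(X, 2, seed=0, n_restarts=10)
        model, _ = fcm(X, 2, m=1.05, seed=0)
        assert adjusted_rand_score(km.labels, model.labels) == 1.0

    def test_m_near_one_equals_kmeans_blobs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.vstack([
                rng.normal(0, 0.5, (15, 2)),
                rng.normal(8, 0.5, (15, 2)),
            ])
            km = kmeans(X, 2, seed=seed, n_restarts=10)
            fm, _ = fcm(X, 2, m=1.05, seed=seed)
            assert adjusted_rand_score(km.labels, fm.labels) == 1.0, seed

    def test_m_must_exceed_one(self):
        with pytest.raises(ValidationError):
            fcm(np.zeros((4, 1)), 2, m=1.0)

    def test_objective_non_increasing(self, rng):
        """FCM objective sum u^m d^2 computed after each sweep never rises."""
        X = rng.normal(0, 1, (40, 2))
        prev = np.inf
        for iters in range(1, 15):
            model, memb = fcm(X, 3, m=2.0, seed=5, max_iter=iters, tol=0.0)
            d2 = cdist(X, model.centroids, "sqeuclidean")
            obj = ((memb.u**memb.m) * d2).sum()
            assert obj <= prev + 1e-9
            prev = obj


class TestMeanShift:
    def test_single_blob_one_mode(self):
        rng = np.random.default_rng(0)
        sigma = 1.0
        X = rng.normal(5.0, sigma, (200, 2))
        model = mean_shift(X, MeanShiftSpec(h=3 * sigma))
        assert model.k == 1
        assert np.linalg.norm(model.centroids[0] - X.mean(axis=0)) < 0.2 * sigma

    def test_two_blobs_two_modes(self):
        rng = np.random.default_rng(1)
        sigma = 0.5
        X = np.vstack([
            rng.normal(0, sigma, (100, 2)),
            rng.normal(20 * sigma, sigma, (100, 2)),
        ])
        model = mean_shift(X, MeanShiftSpec(h=3 * sigma))
        assert model.k == 2
        truth = np.repeat([0, 1], 100)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_flat_kernel_matches_sklearn(self):
        from sklearn.cluster import MeanShift as SkMeanShift

        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.4, (60, 2)), rng.normal(8, 0.4, (60, 2))])
        mine = mean_shift(X, MeanShiftSpec(h=2.0, kernel="flat"))
        ref = SkMeanShift(bandwidth=2.0).fit(X)
        assert adjusted_rand_score(ref.labels_, mine.labels) == 1.0

    def test_row_shuffle_invariance(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.4, (40, 2)), rng.normal(6, 0.4, (40, 2))])
        perm = rng.permutation(len(X))
        a = mean_shift(X, MeanShiftSpec(h=1.5))
        b = mean_shift(X[perm], MeanShiftSpec(h=1.5))
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_invalid_bandwidth(self):
        with pytest.raises(ValidationError):
            MeanShiftSpec(h=0.0)


class TestEstimateBandwidth:
    def test_two_points_quantile_one(self):
        X = np.array([[0.0], [4.0]])
        assert estimate_bandwidth(X, quantile=1.0) == pytest.approx(4.0)

    def test_scales_linearly(self, rng):
        X = rng.normal(0, 1, (50, 3))
        h = estimate_bandwidth(X, 0.3)
        assert estimate_bandwidth(3.0 * X, 0.3) == pytest.approx(3.0 * h, rel=1e-9)

    def test_quantile_zero_error(self, rng):
        with pytest.raises(ValidationError):
            estimate_bandwidth(rng.normal(0, 1, (10, 2)), 0.0)

    def test_single_point_error(self):
        with pytest.raises(ValidationError):
            estimate_bandwidth(np.zeros((1, 2)), 0.5)


def mst_single_linkage_oracle(X, k):
    """Single linkage == cutting the k-1 largest MST edges."""
    D = squareform(pdist(X))
    mst = minimum_spanning_tree(csr_matrix(D)).toarray()
    edges = np.argwhere(mst > 0)
    weights = mst[mst > 0]
    keep = np.argsort(weights)[: len(weights) - (k - 1)]
    adj = np.zeros_like(mst)
    for e in keep:
        i, j = edges[e]
        adj[i, j] = adj[j, i] = 1
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


class TestAgglomerative:
    def test_hand_trace_1d(self):
        X = np.array([0.0, 1.0, 5.0, 6.0])
        model = agglomerative(X, 2, linkage="single")
        assert adjusted_rand_score([0, 0, 1, 1], model.labels) == 1.0

    def test_k_equals_n(self, rng):
        X = rng.normal(0, 1, (7, 2))
        model = agglomerative(X, 7)
        assert len(np.unique(model.labels)) == 7

    def test_single_linkage_equals_mst_oracle(self, rng):
        for n, k in [(20, 3), (50, 4), (30, 2)]:
            X = rng.normal(0, 1, (n, 2))
            model = agglomerative(X, k, linkage="single")
            oracle = mst_single_linkage_oracle(X, k)
            assert adjusted_rand_score(oracle, model.labels) == 1.0

    @pytest.mark.parametrize("link", ["single", "complete", "average", "ward"])
    def test_matches_scipy_linkage(self, link, rng):
        X = rng.normal(0, 1, (40, 3))
        model = agglomerative(X, 4, linkage=link)
        Z = scipy_linkage(X, method=link)
        ref = fcluster(Z, t=4, criterion="maxclust")
        assert adjusted_rand_score(ref, model.labels) == 1.0

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValidationError):
            agglomerative(rng.normal(0, 1, (5, 2)), 6)


def dbscan_graph_oracle(X, eps, min_pts):
    """Independent route: connected components of the eps-graph over core
    points; border points attach to a neighboring core's component."""
    D = squareform(pdist(X))
    neighbors = D <= eps  # includes self (diagonal zero)
    core = neighbors.sum(axis=1) >= min_pts
    n = len(X)
    adj = np.zeros((n, n))
    core_idx = np.flatnonzero(core)
    for i in core_idx:
        for j in core_idx:
            if neighbors[i, j]:
                adj[i, j] = 1
    _, comp = connected_components(csr_matrix(adj), directed=False)
    labels = np.full(n, -1)
    labels[core] = comp[core]
    border = ~core & (neighbors[:, core].any(axis=1))
    for i in np.flatnonzero(border):
        cores_near = core_idx[neighbors[i, core_idx]]
        labels[i] = comp[cores_near[0]]
    return labels, core


class TestDBSCAN:
    def test_isolated_point_is_outlier(self, rng):
        blob = rng.normal(0, 0.2, (10, 2))
        X = np.vstack([blob, [[100.0, 100.0]]])
        model = dbscan(X, DBSCANSpec(eps=1.0, min_pts=3))
        assert model.labels[-1] == -1
        assert np.all(model.labels[:-1] == model.labels[0])

    def test_all_within_eps_single_cluster(self, rng):
        X = rng.normal(0, 0.1, (12, 2))
        model = dbscan(X, DBSCANSpec(eps=5.0, min_pts=12))
        assert model.k == 1
        assert np.all(model.labels == 0)

    def test_min_pts_counts_self(self):
        # 3 points pairwise within eps: each closed ball holds 3 -> all core
        X = np.array([[0.0, 0], [0.5, 0], [1.0, 0]])
        model = dbscan(X, DBSCANSpec(eps=0.6, min_pts=3))
        assert model.k == 1
        assert (model.labels == 0).sum() == 3

    def test_two_blob_graph_oracle(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 0.3, (15, 2)), rng.normal(5, 0.3, (15, 2))])
        model = dbscan(X, DBSCANSpec(eps=1.0, min_pts=3))
        oracle, core = dbscan_graph_oracle(X, 1.0, 3)
        clustered = oracle >= 0
        assert np.array_equal(model.labels >= 0, clustered)
        assert adjusted_rand_score(oracle[clustered], model.labels[clustered]) == 1.0

    def test_100_seeded_instances_match_oracle(self):
        """Outlier set and core partition match on random instances n<=60."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 61))
            X = rng.uniform(0, 10, (n, 2))
            eps = float(rng.uniform(0.5, 2.0))
            mp = int(rng.integers(2, 6))
            model = dbscan(X, DBSCANSpec(eps=eps, min_pts=mp))
            oracle, core = dbscan_graph_oracle(X, eps, mp)
            assert np.array_equal(model.labels == -1, oracle == -1), seed
            assert adjusted_rand_score(oracle[core], model.labels[core]) == 1.0, seed
            # border points join the component of one of their core neighbors
            for i in np.flatnonzero((model.labels >= 0) & ~core):
                near_cores = np.flatnonzero(
                    core & (np.linalg.norm(X - X[i], axis=1) <= eps)
                )
                assert model.labels[i] in model.labels[near_cores]

    def test_row_order_deterministic(self, rng):
        X = rng.uniform(0, 5, (40, 2))
        a = dbscan(X, DBSCANSpec(eps=1.0, min_pts=3))
        b = dbscan(X, DBSCANSpec(eps=1.0, min_pts=3))
        assert np.array_equal(a.labels, b.labels)


class TestCrossAlgorithm:
    def test_parametric_methods_never_emit_outliers(self, rng):
        X = rng.normal(0, 1, (30, 2))
        assert kmeans(X, 3, seed=0).labels.min() >= 0
        assert fcm(X, 3, seed=0)[0].labels.min() >= 0
        assert agglomerative(X, 3).labels.min() >= 0

    def test_row_shuffle_invariance_deterministic_algos(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        perm = rng.permutation(len(X))
        for fit in (
            lambda Y: agglomerative(Y, 2).labels,
            lambda Y: dbscan(Y, DBSCANSpec(eps=1.0, min_pts=3)).labels,
            lambda Y: kmeans(Y, 2, seed=0, n_restarts=10).labels,
        ):
            assert adjusted_rand_score(fit(X)[perm], fit(X[perm])) == 1.0

    def test_run_algorithm_dispatch(self, rng):
        X = rng.normal(0, 1, (20, 2))
        assert run_algorithm(X, "kmeans", k=2).k == 2
        assert run_algorithm(X, "hierarchical", k=3).k == 3
        with pytest.raises(ValidationError):
            run_algorithm(X, "dbscan")  # needs a spec
        with pytest.raises(ValidationError):
            run_algorithm(X, "nope")
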
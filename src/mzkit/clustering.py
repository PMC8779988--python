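"""The five clustering algorithms: k-means, fuzzy C-means, mean shift,
agglomerative hierarchical, and DBSCAN.

All algorithms operate on a :class:`~mzkit.data_model.FeatureMatrix` (or a
plain 2-D array) with Euclidean distances and are deterministic given their
seed.  Outlier label -1 is produced only by the density-based methods.
Tie-breaking everywhere: the lowest cluster index wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .data_model import FeatureMatrix
from .errors import ValidationError

OUTLIER = -1


@dataclass
class ClusterModel:
    labels: np.ndarray
    centroids: np.ndarray | None
    k: int
    iterations_run: int = 0
    converged: bool = True
    seed: int | None = None
    inertia: float | None = None


@dataclass
class FuzzyMembership:
    u: np.ndarray  # n x k, rows sum to 1
    m: float       # fuzziness coefficient > 1


@dataclass
class MeanShiftSpec:
    h: float
    kernel: str = "gaussian"
    seeds: np.ndarray | None = None  # default: all points
    max_iter: int = 300
    mode_merge_tol: float | None = None  # default: h
    tol: float | None = None             # default: 1e-3 * h

    def __post_init__(self):
        if self.h <= 0:
            raise ValidationError("bandwidth h must be > 0")
        if self.kernel not in ("gaussian", "flat"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if self.mode_merge_tol is None:
            self.mode_merge_tol = self.h
        if self.mode_merge_tol <= 0:
            raise ValidationError("mode_merge_tol must be > 0")
        if self.tol is None:
            self.tol = 1e-3 * self.h


@dataclass
class DBSCANSpec:
    eps: float
    min_pts: int = 3

    def __post_init__(self):
        if self.eps <= 0:
            raise ValidationError("eps must be > 0")
        if self.min_pts < 1:
            raise ValidationError("min_pts must be >= 1")


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


# ---------------------------------------------------------------- k-means


def _kmeans_single(X: np.ndarray, k: int, rng: np.random.Generator,
                   max_iter: int, init: str = "points",
                   ) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    n = len(X)
    if init == "points":
        # k distinct data rows
        init_idx = rng.choice(n, size=k, replace=False)
        centroids = X[init_idx].copy()
    else:
        # random partition: means of a random k-way split (covers Lloyd
        # fixed points unreachable from any data-point init)
        part = rng.integers(0, k, n)
        part[rng.choice(n, size=k, replace=False)] = np.arange(k)  # no empty cluster
        centroids = np.array([X[part == j].mean(axis=0) for j in range(k)])
    labels = np.full(n, -1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        new_labels = d2.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for j in range(k):
            members = labels == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its centroid
                dist_own = d2[np.arange(n), labels]
                far = int(dist_own.argmax())
                centroids[j] = X[far]
                labels[far] = j
    labels, centroids = _hartigan_refine(X, labels, centroids)
    d2 = cdist(X, centroids, metric="sqeuclidean")
    sse = float(d2[np.arange(n), labels].sum())
    return labels, centroids, sse, it, converged


def _hartigan_refine(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray,
                     max_moves: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Single-point improvement moves after Lloyd convergence.

    Moving x from cluster a (size n_a) to b changes the SSE by
    n_b/(n_b+1) ||x-mu_b||^2 - n_a/(n_a-1) ||x-mu_a||^2; the best improving
    move is applied until none remains.  The SSE-optimal partition is always
    stable under such moves, while Lloyd fixed points need not be, so this
    escapes many Lloyd-only local optima.
    """
    n, k = len(X), len(centroids)
    if k < 2:
        return labels, centroids
    labels = labels.copy()
    centroids = centroids.copy()
    sizes = np.bincount(labels, minlength=k).astype(float)
    if max_moves is None:
        max_moves = 10 * n + 100
    for _ in range(max_moves):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        own = d2[np.arange(n), labels]
        with np.errstate(divide="ignore", invalid="ignore"):
            # singleton clusters may not be emptied (keeps k clusters): -inf
            # removal benefit makes every move away from them non-improving
            removal = np.where(sizes[labels] > 1,
                               sizes[labels] / (sizes[labels] - 1.0) * own, -np.inf)
            gain = sizes / (sizes + 1.0) * d2  # cost of joining each cluster
        delta = gain - removal[:, None]
        delta[np.arange(n), labels] = 0.0
        best_flat = int(np.argmin(delta))
        i, b = divmod(best_flat, k)
        if delta[i, b] >= -1e-12:
            break
        a = labels[i]
        centroids[a] = (centroids[a] * sizes[a] - X[i]) / (sizes[a] - 1.0)
        centroids[b] = (centroids[b] * sizes[b] + X[i]) / (sizes[b] + 1.0)
        sizes[a] -= 1.0
        sizes[b] += 1.0
        labels[i] = b
    return labels, centroids


def kmeans(X, k: int, seed: int = 0, max_iter: int = 300,
           n_restarts: int = 10) -> ClusterModel:
    """Lloyd iteration minimizing within-cluster SSE; best of ``n_restarts``."""
    X = _as_array(X)
    n = len(X)
    if k < 1 or k > n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        init = "points" if restart % 2 == 0 else "partition"
        labels, centroids, sse, it, conv = _kmeans_single(X, k, rng, max_iter, init)
        if best is None or sse < best[2] - 1e-12:
            best = (labels, centroids, sse, it, conv)
    labels, centroids, sse, it, conv = best
    return ClusterModel(labels=labels, centroids=centroids, k=k,
                        iterations_run=it, converged=conv, seed=seed, inertia=sse)


# ---------------------------------------------------------------- fuzzy C-means


def fcm(X, k: int, m: float = 2.0, seed: int = 0, max_iter: int = 300,
        tol: float = 1e-6) -> tuple[ClusterModel, FuzzyMembership]:
    """Fuzzy C-means.

    Iterates the membership update
    ``u_ij = 1 / sum_l (||x_i - mu_j|| / ||x_i - mu_l||)^(2/(m-1))`` and the
    weighted-centroid update ``mu_j = sum u_ij^m x_i / sum u_ij^m`` until the
    maximum membership change drops below ``tol``.  Hard labels are the
    highest-membership cluster.  A point coinciding with a centroid takes
    membership 1 there (the m -> limit convention).
    """
    X = _as_array(X)
    n = len(X)
    if m <= 1:
        raise ValidationError("fuzziness coefficient m must be > 1")
    if k < 1 or k > n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    exponent = 2.0 / (m - 1.0)
    u = np.full((n, k), 1.0 / k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = cdist(X, centroids)
        zero = d < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-exponent)
            new_u = inv / inv.sum(axis=1, keepdims=True)
        at_centroid = zero.any(axis=1)
        if at_centroid.any():
            new_u[at_centroid] = 0.0
            first = zero[at_centroid].argmax(axis=1)
            new_u[np.flatnonzero(at_centroid), first] = 1.0
        delta = np.abs(new_u - u).max()
        u = new_u
        w = u**m
        centroids = (w.T @ X) / w.sum(axis=0)[:, None]
        if delta < tol:
            converged = True
            break
    labels = u.argmax(axis=1)
    d2 = cdist(X, centroids, metric="sqeuclidean")
    inertia = float(((u**m) * d2).sum())
    model = ClusterModel(labels=labels, centroids=centroids, k=k,
                         iterations_run=it, converged=converged, seed=seed,
                         inertia=inertia)
    return model, FuzzyMembership(u=u, m=m)


# ---------------------------------------------------------------- mean shift


def estimate_bandwidth(X, quantile: float = 0.3) -> float:
    """Mean distance to the ceil(quantile * n)-th nearest neighbor (self counts)."""
    X = _as_array(X)
    n = len(X)
    if n < 2:
        raise ValidationError("need at least 2 points to estimate a bandwidth")
    if not 0 < quantile <= 1:
        raise ValidationError("quantile must be in (0, 1]")
    knn = max(int(np.ceil(quantile * n)), 2)
    tree = cKDTree(X)
    dist, _ = tree.query(X, k=knn)
    return float(dist[:, -1].mean())


def mean_shift(X, spec: MeanShiftSpec) -> ClusterModel:
    """Mode seeking: every seed moves to the kernel-weighted mean of its
    neighborhood until displacement < tol; nearby modes are merged and each
    point joins the closest mode."""
    X = _as_array(X)
    n = len(X)
    seeds = X.copy() if spec.seeds is None else np.asarray(spec.seeds, float).copy()
    h = spec.h
    tree = cKDTree(X) if spec.kernel == "flat" else None
    active = np.ones(len(seeds), dtype=bool)
    frozen_empty = np.zeros(len(seeds), dtype=bool)
    for _ in range(spec.max_iter):
        if not active.any():
            break
        s = seeds[active]
        if spec.kernel == "gaussian":
            d2 = cdist(s, X, metric="sqeuclidean")
            w = np.exp(-0.5 * d2 / h**2)
            new_s = (w @ X) / w.sum(axis=1)[:, None]
        else:
            new_s = s.copy()
            for i, si in enumerate(s):
                idx = tree.query_ball_point(si, h)
                if not idx:
                    frozen_empty[np.flatnonzero(active)[i]] = True
                    continue
                new_s[i] = X[idx].mean(axis=0)
        moved = np.linalg.norm(new_s - s, axis=1) >= spec.tol
        seeds[active] = new_s
        idx_active = np.flatnonzero(active)
        active[idx_active] = moved & ~frozen_empty[idx_active]
    if frozen_empty.any():
        warnings.warn(f"{int(frozen_empty.sum())} seeds had empty flat-kernel "
                      "neighborhoods and were frozen in place")
    # merge modes within mode_merge_tol, in seed order (lowest index wins)
    modes: list[np.ndarray] = []
    assign = np.empty(len(seeds), dtype=int)
    for i, s in enumerate(seeds):
        for j, mode in enumerate(modes):
            if np.linalg.norm(s - mode) <= spec.mode_merge_tol:
                assign[i] = j
                break
        else:
            assign[i] = len(modes)
            modes.append(s)
    modes_arr = np.array(modes)
    d = cdist(X, modes_arr)
    labels = d.argmin(axis=1)
    # drop empty modes, renumber in first-seed order
    used = np.unique(labels)
    remap = {old: new for new, old in enumerate(used)}
    labels = np.array([remap[v] for v in labels])
    centroids = modes_arr[used]
    return ClusterModel(labels=labels, centroids=centroids, k=len(used),
                        iterations_run=spec.max_iter, converged=not active.any())


# ---------------------------------------------------------------- hierarchical


_LINKAGES = ("single", "complete", "average", "ward")


def agglomerative(X, k: int, linkage: str = "single") -> ClusterModel:
    """Bottom-up merging: repeatedly join the closest pair of clusters under
    the chosen linkage until k clusters remain (Lance-Williams updates on a
    full distance matrix)."""
    X = _as_array(X)
    n = len(X)
    if linkage not in _LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}")
    if k < 1 or k > n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    labels = np.arange(n)
    if k == n:
        return ClusterModel(labels=labels, centroids=X.copy(), k=k)
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    n_clusters = n
    while n_clusters > k:
        flat = np.argmin(D)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        # merge j into i (lowest index keeps the cluster)
        labels[labels == j] = i
        others = alive.copy()
        others[[i, j]] = False
        di, dj = D[i, others], D[j, others]
        if linkage == "single":
            new = np.minimum(di, dj)
        elif linkage == "complete":
            new = np.maximum(di, dj)
        elif linkage == "average":
            new = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        else:  # ward
            nk = sizes[others]
            ni, nj = sizes[i], sizes[j]
            dij = D[i, j]
            new = np.sqrt(
                ((nk + ni) * di**2 + (nk + nj) * dj**2 - nk * dij**2)
                / (nk + ni + nj)
            )
        D[i, others] = new
        D[others, i] = new
        D[j, :] = np.inf
        D[:, j] = np.inf
        sizes[i] += sizes[j]
        alive[j] = False
        n_clusters -= 1
    # renumber cluster ids to 0..k-1 in first-row order
    _, labels = np.unique(labels, return_inverse=True)
    order = {}
    final = np.empty(n, dtype=int)
    for idx, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        final[idx] = order[lab]
    centroids = np.array([X[final == c].mean(axis=0) for c in range(k)])
    return ClusterModel(labels=final, centroids=centroids, k=k)


# ---------------------------------------------------------------- DBSCAN


def dbscan(X, spec: DBSCANSpec) -> ClusterModel:
    """Density-reachability expansion.

    A point whose closed eps-ball (itself included) holds >= min_pts points is
    a core point; clusters grow from core points in row order, so the result
    is deterministic.  Low-density points not reached by any cluster get -1.
    """
    X = _as_array(X)
    n = len(X)
    tree = cKDTree(X)
    neighbors = tree.query_ball_point(X, spec.eps)  # closed ball, includes self
    core = np.array([len(nb) >= spec.min_pts for nb in neighbors])
    labels = np.full(n, OUTLIER)
    visited = np.zeros(n, dtype=bool)
    current = 0
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        # expand a new cluster from this core point
        visited[i] = True
        labels[i] = current
        queue = [i]
        while queue:
            p = queue.pop(0)
            for q in neighbors[p]:
                if labels[q] == OUTLIER:
                    labels[q] = current
                if not visited[q] and core[q]:
                    visited[q] = True
                    queue.append(q)
        current += 1
    centroids = None
    if current > 0:
        centroids = np.array([X[labels == c].mean(axis=0) for c in range(current)])
    return ClusterModel(labels=labels, centroids=centroids, k=current)


# ---------------------------------------------------------------- dispatch


def run_algorithm(X, algorithm: str, *, k: int = 4, seed: int = 0,
                  fcm_m: float = 2.0, meanshift_spec: MeanShiftSpec | None = None,
                  meanshift_quantile: float = 0.3,
                  dbscan_spec: DBSCANSpec | None = None,
                  linkage: str = "single", n_restarts: int = 10,
                  max_iter: int = 300) -> ClusterModel:
    """Uniform entry point used by the scenario runner."""
    if algorithm == "kmeans":
        return kmeans(X, k, seed=seed, max_iter=max_iter, n_restarts=n_restarts)
    if algorithm == "fcm":
        model, _ = fcm(X, k, m=fcm_m, seed=seed, max_iter=max_iter)
        return model
    if algorithm == "meanshift":
        if meanshift_spec is None:
            meanshift_spec = MeanShiftSpec(h=estimate_bandwidth(X, meanshift_quantile))
        return mean_shift(X, meanshift_spec)
    if algorithm == "hierarchical":
        return agglomerative(X, k, linkage=linkage)
    if algorithm == "dbscan":
        if dbscan_spec is None:
            raise ValidationError("dbscan requires a DBSCANSpec (eps, min_pts)")
        return dbscan(X, dbscan_spec)
    raise ValidationError(f"unknown algorithm {algorithm!r}")
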
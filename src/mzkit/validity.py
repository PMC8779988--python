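"""Cluster-validity scoring: Davies-Bouldin index, Silhouette index, and the
variance reduction index (VRI).

Conventions: outlier rows/cells (label -1) are excluded from every metric;
DBI and Silhouette are undefined ("n.v.") when fewer than 2 clusters remain,
in which case VRI is 0 for a single cluster.  VRI uses population (1/N)
variances and is computed on RAW attribute rasters, never on normalized
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import AttributeRasterStack, FeatureMatrix, LabelRaster
from .errors import ValidationError

OUTLIER = -1


@dataclass
class ValidityReport:
    dbi: float | None            # None = "n.v."
    silhouette: float | None
    vri_per_attribute: dict[str, float] = field(default_factory=dict)
    vri_mean: float | None = None
    n_clusters_effective: int = 0
    n_outliers_excluded: int = 0

    def as_row(self) -> dict:
        nv = lambda v: "n.v." if v is None else v
        return {
            "DBI": nv(self.dbi),
            "Silhouette": nv(self.silhouette),
            "VRI": 0.0 if self.vri_mean is None else self.vri_mean,
            "n_clusters": self.n_clusters_effective,
            "n_outliers": self.n_outliers_excluded,
        }


def _clean(X, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValidationError("labels length does not match data")
    keep = labels != OUTLIER
    uniq = np.unique(labels[keep])
    return X[keep], labels[keep], uniq


def davies_bouldin(X, labels) -> float | None:
    """DBI = (1/k) sum_i max_{j != i} (s_i + s_j) / d_ij.

    s_i is the mean distance of cluster-i members to their centroid, d_ij the
    distance between centroids.  Returns None (n.v.) for fewer than 2 clusters.
    """
    X, labels, uniq = _clean(X, labels)
    k = len(uniq)
    if k < 2:
        return None
    centroids = np.array([X[labels == c].mean(axis=0) for c in uniq])
    s = np.array([
        cdist(X[labels == c], centroids[i : i + 1]).mean() for i, c in enumerate(uniq)
    ])
    d = cdist(centroids, centroids)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (s[:, None] + s[None, :]) / d  # diagonal 0/0 discarded below
    np.fill_diagonal(ratio, -np.inf)
    return float(ratio.max(axis=1).mean())


def silhouette(X, labels) -> float | None:
    """Mean Silhouette s(i) = (b(i) - a(i)) / max(a(i), b(i)).

    a(i): mean distance to own-cluster members (self excluded); b(i): smallest
    mean distance to another cluster.  Singleton clusters contribute s(i) = 0.
    """
    X, labels, uniq = _clean(X, labels)
    k = len(uniq)
    if k < 2:
        return None
    n = len(X)
    D = cdist(X, X)
    sizes = {c: int((labels == c).sum()) for c in uniq}
    # mean distance from every point to every cluster
    mean_to = np.empty((n, k))
    for idx, c in enumerate(uniq):
        mean_to[:, idx] = D[:, labels == c].mean(axis=1)
    s = np.zeros(n)
    for i in range(n):
        ci = np.flatnonzero(uniq == labels[i])[0]
        size = sizes[labels[i]]
        if size == 1:
            s[i] = 0.0
            continue
        a = mean_to[i, ci] * size / (size - 1)  # exclude the zero self-distance
        b = np.min(np.delete(mean_to[i], ci))
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom  # coincident points
    return float(s.mean())


def vri_from_arrays(values_by_attr: dict[str, np.ndarray], labels: np.ndarray
                    ) -> tuple[dict[str, float], float | None]:
    """VRI per attribute from flat arrays (one value per non-outlier unit).

    VRI_theta = (1 - sum_i A_i * v_Ci / v) * 100 with A_i the cluster area
    fraction and population variances; attributes with zero overall variance
    are skipped with a warning.
    """
    labels = np.asarray(labels)
    keep = labels != OUTLIER
    labels = labels[keep]
    if len(labels) == 0:
        raise ValidationError("no non-outlier units")
    uniq = np.unique(labels)
    per_attr: dict[str, float] = {}
    for name, vals in values_by_attr.items():
        vals = np.asarray(vals, float)[keep]
        v = vals.var()  # population variance
        if v == 0:
            warnings.warn(f"attribute {name!r} has zero overall variance; skipped")
            continue
        weighted = sum(
            (labels == c).sum() / len(labels) * vals[labels == c].var() for c in uniq
        )
        per_attr[name] = float((1.0 - weighted / v) * 100.0)
    mean = float(np.mean(list(per_attr.values()))) if per_attr else None
    return per_attr, mean


def vri(stack: AttributeRasterStack, labels: LabelRaster,
        attrs: list[str] | None = None) -> tuple[dict[str, float], float | None]:
    """VRI on raw attribute rasters against a label raster (aligned grids)."""
    if labels.geometry != stack.geometry:
        raise ValidationError("label raster not aligned with attribute stack")
    if attrs is None:
        attrs = stack.attribute_names
    mask = stack.mask & labels.mask
    flat = {a: stack.layers[a][mask] for a in attrs}
    return vri_from_arrays(flat, labels.labels[mask])


def evaluate_labeling(X, labels, values_by_attr: dict[str, np.ndarray] | None = None
                      ) -> ValidityReport:
    """Full ValidityReport for one labeling.

    ``X`` is the clustering feature space (DBI/Silhouette are measured there);
    ``values_by_attr`` are raw per-unit attribute values for VRI.
    """
    labels = np.asarray(labels)
    n_out = int((labels == OUTLIER).sum())
    uniq = np.unique(labels[labels != OUTLIER])
    report = ValidityReport(
        dbi=davies_bouldin(X, labels),
        silhouette=silhouette(X, labels),
        n_clusters_effective=len(uniq),
        n_outliers_excluded=n_out,
    )
    if values_by_attr is not None:
        per_attr, mean = vri_from_arrays(values_by_attr, labels)
        report.vri_per_attribute = per_attr
        report.vri_mean = 0.0 if len(uniq) < 2 else mean
    return report


def evaluate_scenarios(stack: AttributeRasterStack, scenarios, config: dict | None = None):
    """Score a list of scenarios on one attribute stack.

    Returns a list of row dicts (scenario, DBI, Silhouette, VRI, ...) mirroring
    a per-field evaluation table; a failing scenario yields an error row
    instead of aborting the sweep.  DBI/Silhouette are measured in each
    scenario's own feature space; VRI always on the raw attribute rasters.
    """
    from . import clustering as cl
    from .preprocessing import build_feature_matrix

    config = dict(config or {})
    k = int(config.get("k", 4))
    seed = int(config.get("seed", 0))
    priority = config.get("priority")
    threshold = float(config.get("threshold", 0.7))
    raw_values = {a: stack.layers[a][stack.mask] for a in stack.attribute_names}
    rows = []
    for scenario in scenarios:
        row = {"scenario": scenario.name}
        try:
            matrix, _ = build_feature_matrix(stack, scenario, priority, threshold)
            ms_spec = None
            if scenario.algorithm == "meanshift" and config.get("meanshift_h"):
                ms_spec = cl.MeanShiftSpec(h=float(config["meanshift_h"]))
            db_spec = None
            if scenario.algorithm == "dbscan":
                db_spec = cl.DBSCANSpec(
                    eps=float(config.get("dbscan_eps", 0.5)),
                    min_pts=int(config.get("dbscan_min_pts", 3)),
                )
            model = cl.run_algorithm(
                matrix, scenario.algorithm, k=k, seed=seed,
                fcm_m=float(config.get("fcm_m", 2.0)),
                meanshift_spec=ms_spec,
                meanshift_quantile=float(config.get("meanshift_quantile", 0.3)),
                dbscan_spec=db_spec,
                linkage=config.get("linkage", "single"),
                n_restarts=int(config.get("n_restarts", 10)),
            )
            report = evaluate_labeling(matrix, model.labels, raw_values)
            row.update(report.as_row())
        except Exception as exc:  # isolate scenario failures
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return rows
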
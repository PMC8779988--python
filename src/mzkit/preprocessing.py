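"""Range normalization, cross-correlation feature selection, and scenario
feature-matrix assembly.

Scenario naming grammar: ``<algorithm>-<norm><coords>[-dec]`` where the
normalization token is ``nn``/``wn`` and the coordinate token is ``nc``/``wc``.
With feature decrease the name drops the normalization token
(``<algorithm>-nc-dec``): decreased scenarios are always normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import AttributeRasterStack, FeatureMatrix
from .errors import ValidationError

ALGORITHMS = ("kmeans", "fcm", "meanshift", "hierarchical", "dbscan")

_ALG_TOKEN = {
    "kmeans": "kmeans",
    "fcm": "fcm",
    "meanshift": "ms",
    "hierarchical": "hier",
    "dbscan": "dbscan",
}
_TOKEN_ALG = {v: k for k, v in _ALG_TOKEN.items()}


@dataclass(frozen=True)
class ScenarioSpec:
    """One clustering scenario: algorithm plus input-data format flags."""

    algorithm: str
    normalize: bool = True
    include_coords: bool = False
    feature_decrease: bool = False

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if not self.normalize and self.algorithm != "kmeans":
            raise ValidationError("un-normalized input is only evaluated with kmeans")
        if not self.normalize and (self.include_coords or self.feature_decrease):
            raise ValidationError("the un-normalized scenario is kmeans-nn-nc only")

    @property
    def name(self) -> str:
        alg = _ALG_TOKEN[self.algorithm]
        coords = "wc" if self.include_coords else "nc"
        if self.feature_decrease:
            return f"{alg}-{coords}-dec"
        norm = "wn" if self.normalize else "nn"
        return f"{alg}-{norm}-{coords}"

    @classmethod
    def from_name(cls, name: str) -> "ScenarioSpec":
        parts = name.lower().split("-")
        if len(parts) != 3 or parts[0] not in _TOKEN_ALG:
            raise ValidationError(f"invalid scenario name {name!r}")
        alg = _TOKEN_ALG[parts[0]]
        if parts[2] == "dec":
            if parts[1] not in ("nc", "wc"):
                raise ValidationError(f"invalid scenario name {name!r}")
            return cls(alg, normalize=True, include_coords=parts[1] == "wc",
                       feature_decrease=True)
        if parts[1] not in ("nn", "wn") or parts[2] not in ("nc", "wc"):
            raise ValidationError(f"invalid scenario name {name!r}")
        return cls(alg, normalize=parts[1] == "wn", include_coords=parts[2] == "wc",
                   feature_decrease=False)


def standard_scenarios() -> list[ScenarioSpec]:
    """The 21-scenario evaluation grid: kmeans in 5 formats, the other four
    algorithms in 4 formats each (all normalized)."""
    grid = [ScenarioSpec("kmeans", normalize=False)]
    for alg in ALGORITHMS:
        grid.append(ScenarioSpec(alg, include_coords=False))
        grid.append(ScenarioSpec(alg, include_coords=True))
        grid.append(ScenarioSpec(alg, include_coords=False, feature_decrease=True))
        grid.append(ScenarioSpec(alg, include_coords=True, feature_decrease=True))
    return grid


@dataclass
class SelectionReport:
    """Audit of correlation-based feature selection."""

    correlation: np.ndarray
    attribute_names: list[str]
    threshold: float
    priority: list[str]
    kept: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)


def range_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Scale every column into [0, 1]; constant columns map to zeros."""
    if matrix.n == 0:
        raise ValidationError("empty feature matrix")
    vals = matrix.values.copy()
    normalizers: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(matrix.columns):
        lo, hi = vals[:, j].min(), vals[:, j].max()
        normalizers[name] = (float(lo), float(hi))
        if hi == lo:
            warnings.warn(f"constant column {name!r} normalized to zeros")
            vals[:, j] = 0.0
        else:
            vals[:, j] = (vals[:, j] - lo) / (hi - lo)
    return FeatureMatrix(
        values=vals,
        columns=list(matrix.columns),
        row_index=matrix.row_index,
        normalized=True,
        normalizers=normalizers,
    )


def correlation_matrix(matrix: FeatureMatrix) -> np.ndarray:
    """Pairwise Pearson correlation; symmetric with exact unit diagonal."""
    if matrix.n < 2:
        raise ValidationError("need at least 2 rows for correlation")
    for j, name in enumerate(matrix.columns):
        if np.ptp(matrix.values[:, j]) == 0:
            raise ValidationError(f"Pearson correlation undefined for constant column {name!r}")
    r = np.corrcoef(matrix.values, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def select_features(
    correlation: np.ndarray,
    attribute_names: list[str],
    priority: list[str],
    threshold: float = 0.7,
) -> SelectionReport:
    """Greedy priority-ordered selection dropping highly correlated attributes.

    Attributes are visited in priority order; one is kept iff its |r| against
    every already-kept attribute is <= threshold.
    """
    missing = [a for a in attribute_names if a not in priority]
    if missing:
        raise ValidationError(f"attributes missing from priority order: {missing}")
    idx = {a: i for i, a in enumerate(attribute_names)}
    kept: list[str] = []
    removed: list[str] = []
    for attr in priority:
        if attr not in idx:
            continue
        i = idx[attr]
        if all(abs(correlation[i, idx[k]]) <= threshold for k in kept):
            kept.append(attr)
        else:
            removed.append(attr)
    return SelectionReport(
        correlation=correlation,
        attribute_names=list(attribute_names),
        threshold=threshold,
        priority=list(priority),
        kept=kept,
        removed=removed,
    )


def stack_to_matrix(stack: AttributeRasterStack, attrs: list[str] | None = None,
                    include_coords: bool = False) -> FeatureMatrix:
    """Flatten in-mask cells of a raster stack into feature rows (raw units)."""
    if attrs is None:
        attrs = stack.attribute_names
    mask = stack.mask
    cols = [stack.layers[a][mask] for a in attrs]
    names = list(attrs)
    if include_coords:
        cx, cy = stack.geometry.cell_centers()
        cols += [cx[mask], cy[mask]]
        names += ["x", "y"]
    row_index = np.flatnonzero(mask.ravel())
    return FeatureMatrix(np.column_stack(cols), names, row_index=row_index)


def build_feature_matrix(
    stack: AttributeRasterStack,
    scenario: ScenarioSpec,
    priority: list[str] | None = None,
    threshold: float = 0.7,
) -> tuple[FeatureMatrix, SelectionReport | None]:
    """Assemble the clustering input for one scenario.

    Feature selection (when requested) screens the soil attributes only;
    coordinate columns, when included under normalization, are range-normalized
    like any other column.
    """
    if not stack.attribute_names:
        raise ValidationError("empty raster stack")
    attrs = stack.attribute_names
    report = None
    if scenario.feature_decrease:
        if priority is None:
            priority = list(attrs)
        raw = stack_to_matrix(stack, attrs)
        corr = correlation_matrix(raw)
        report = select_features(corr, attrs, priority, threshold)
        attrs = [a for a in attrs if a in report.kept]
    matrix = stack_to_matrix(stack, attrs, include_coords=scenario.include_coords)
    if scenario.normalize:
        matrix = range_normalize(matrix)
    return matrix, report
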
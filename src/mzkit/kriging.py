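"""Semivariogram estimation/fitting and ordinary kriging onto a common grid.

The prediction at a location is a linear combination of nearby measurements;
the weights come from a fitted semivariogram model through the ordinary-kriging
system with the sum-to-one unbiasedness constraint (Lagrange multiplier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .data_model import AttributeRasterStack, GridGeometry, PointSampleSet, RasterLayer
from .errors import FitError, NumericError, ValidationError

VARIOGRAM_FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass
class EmpiricalVariogram:
    lag_centers: np.ndarray  # meters, strictly increasing
    gamma: np.ndarray        # semivariance per lag, attribute units^2
    pair_counts: np.ndarray

    def __post_init__(self):
        self.lag_centers = np.asarray(self.lag_centers, float)
        self.gamma = np.asarray(self.gamma, float)
        self.pair_counts = np.asarray(self.pair_counts, int)
        if np.any(np.diff(self.lag_centers) <= 0):
            raise ValidationError("lag centers must be strictly increasing")
        if (self.gamma < 0).any():
            raise ValidationError("semivariance must be non-negative")


@dataclass
class VariogramModel:
    """Bounded variogram model gamma(h) = nugget + partial_sill * f(h / range)."""

    family: str
    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self):
        if self.family not in VARIOGRAM_FAMILIES:
            raise ValidationError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValidationError("nugget and partial sill must be >= 0")
        if self.range_m <= 0:
            raise ValidationError("range must be > 0")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, float)
        r = self.range_m
        if self.family == "spherical":
            hr = np.minimum(h / r, 1.0)
            structure = 1.5 * hr - 0.5 * hr**3
        elif self.family == "exponential":
            structure = 1.0 - np.exp(-3.0 * h / r)
        else:  # gaussian
            structure = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        gamma = self.nugget + self.partial_sill * structure
        return np.where(h == 0, 0.0, gamma)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


def empirical_semivariogram(
    points: PointSampleSet,
    attr: str,
    n_lags: int = 15,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Classical (Matheron) estimator: gamma_b = sum (z_i - z_j)^2 / (2 N_b).

    Pairs are binned by separation distance into ``n_lags`` equal-width bins up
    to ``max_lag`` (default: half the maximum pairwise distance). Empty bins
    are dropped.
    """
    if points.n < 2:
        raise ValidationError("need at least 2 points")
    z = points.attributes[attr]
    d = pdist(points.coords())
    dmax = d.max()
    if dmax == 0:
        raise ValidationError("all points coincident: degenerate geometry")
    if max_lag is None:
        max_lag = dmax / 2.0
    if max_lag <= 0:
        raise ValidationError("max_lag must be > 0")
    sqdiff = pdist(z[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    # pairs exactly at max_lag fall in the last bin
    which = np.digitize(d, edges[1:-1], right=False)
    in_range = d <= max_lag
    counts = np.bincount(which[in_range], minlength=n_lags)
    sums = np.bincount(which[in_range], weights=sqdiff[in_range], minlength=n_lags)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    gamma = np.zeros(n_lags)
    gamma[keep] = sums[keep] / (2.0 * counts[keep])
    return EmpiricalVariogram(centers[keep], gamma[keep], counts[keep])


def fit_variogram(emp: EmpiricalVariogram, family: str = "spherical") -> VariogramModel:
    """Pair-count-weighted least-squares fit of a variogram model."""
    if family not in VARIOGRAM_FAMILIES:
        raise ValidationError(f"unknown variogram family {family!r}")
    h = emp.lag_centers
    g = emp.gamma
    w = np.sqrt(emp.pair_counts.astype(float))
    if len(h) < 3:
        raise ValidationError("need at least 3 non-empty lag bins to fit")
    max_lag = h[-1]
    gmax = g.max()
    if gmax == 0:
        return VariogramModel(family, 0.0, 0.0, max_lag)
    scale = gmax

    def residuals(p):
        nugget, psill, rng = p
        model = VariogramModel(family, max(nugget, 0.0), max(psill, 0.0), max(rng, 1e-12))
        return w * (model(h) - g) / scale

    starts = [
        (g[0], max(gmax - g[0], 1e-9 * scale), max_lag / 2.0),
        (0.0, gmax, max_lag / 3.0),
        (0.5 * gmax, 0.5 * gmax, max_lag),
    ]
    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                residuals,
                p0,
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 2.0 * max_lag]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("variogram fit did not converge", {"family": family, "n_bins": len(h)})
    nugget, psill, rng = best.x
    return VariogramModel(family, float(nugget), float(psill), float(rng))


def _dedupe(coords: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average attribute values at duplicate coordinates (OK matrix singularity)."""
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, z
    warnings.warn(f"{len(coords) - len(uniq)} duplicate sample locations averaged")
    sums = np.bincount(inverse, weights=z, minlength=len(uniq))
    counts = np.bincount(inverse, minlength=len(uniq))
    return uniq, sums / counts


def solve_ok_weights(
    sample_coords: np.ndarray, target: np.ndarray, vmodel: VariogramModel
) -> tuple[np.ndarray, float]:
    """Solve the ordinary-kriging system for one target location.

    Returns (weights, lagrange multiplier); weights sum to 1 exactly up to
    solver precision.
    """
    m = len(sample_coords)
    gamma_ss = vmodel(squareform(pdist(sample_coords)))
    gamma_st = vmodel(np.linalg.norm(sample_coords - target, axis=1))
    lhs = np.empty((m + 1, m + 1))
    lhs[:m, :m] = gamma_ss
    lhs[m, :m] = 1.0
    lhs[:m, m] = 1.0
    lhs[m, m] = 0.0
    rhs = np.append(gamma_st, 1.0)
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"singular kriging matrix: {exc}") from exc
    return sol[:m], sol[m]


def ordinary_krige(
    points: PointSampleSet,
    attr: str,
    vmodel: VariogramModel,
    geometry: GridGeometry,
    neighborhood: int = 32,
    mask: np.ndarray | None = None,
) -> RasterLayer:
    """Ordinary kriging of one attribute onto the grid.

    Per in-mask cell, the OK system is solved over the ``neighborhood`` nearest
    sample points. ``neighborhood`` >= number of points gives the global solve.
    """
    if neighborhood < 2:
        raise ValidationError("neighborhood must be >= 2")
    coords, z = _dedupe(points.coords(), points.attributes[attr])
    n = len(coords)
    nb = min(neighborhood, n)
    if mask is None:
        mask = np.ones(geometry.shape, dtype=bool)
    cx, cy = geometry.cell_centers()
    targets = np.column_stack([cx[mask], cy[mask]])
    tree = cKDTree(coords)
    _, neigh_idx = tree.query(targets, k=nb)
    neigh_idx = np.atleast_2d(neigh_idx)
    if nb == 1:
        neigh_idx = neigh_idx.reshape(-1, 1)
    neigh_idx = np.sort(neigh_idx, axis=1)  # canonical order -> better grouping

    values = np.full(geometry.shape, np.nan)
    out = np.empty(len(targets))
    # group cells by identical neighbor set: one matrix factorization per group
    order = np.lexsort(neigh_idx.T[::-1])
    sorted_idx = neigh_idx[order]
    group_breaks = np.flatnonzero(np.any(np.diff(sorted_idx, axis=0) != 0, axis=1)) + 1
    groups = np.split(order, group_breaks)
    for grp in groups:
        idx = neigh_idx[grp[0]]
        sc = coords[idx]
        m = len(idx)
        gamma_ss = vmodel(squareform(pdist(sc)))
        lhs = np.empty((m + 1, m + 1))
        lhs[:m, :m] = gamma_ss
        lhs[m, :m] = 1.0
        lhs[:m, m] = 1.0
        lhs[m, m] = 0.0
        tg = targets[grp]
        gamma_st = vmodel(np.linalg.norm(sc[None, :, :] - tg[:, None, :], axis=2))
        rhs = np.concatenate([gamma_st, np.ones((len(grp), 1))], axis=1)
        try:
            sol = np.linalg.solve(lhs, rhs.T).T
        except np.linalg.LinAlgError as exc:
            raise NumericError(f"singular kriging matrix: {exc}") from exc
        out[grp] = sol[:, :m] @ z[idx]
    values[mask] = out
    return RasterLayer(geometry, values, mask)


def coverage_mask(
    points: PointSampleSet, geometry: GridGeometry, mask_radius: float
) -> np.ndarray:
    """Cells whose center lies within ``mask_radius`` of any sample point."""
    cx, cy = geometry.cell_centers()
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    tree = cKDTree(points.coords())
    dist, _ = tree.query(centers, k=1)
    return (dist <= mask_radius).reshape(geometry.shape)


def points_to_stack(
    points: PointSampleSet,
    geometry: GridGeometry,
    vmodels: dict[str, VariogramModel] | None = None,
    attrs: list[str] | None = None,
    neighborhood: int = 32,
    mask_radius: float = 24.0,
    variogram_family: str = "spherical",
    n_lags: int = 15,
    max_lag: float | None = None,
) -> AttributeRasterStack:
    """Krige every requested attribute onto the common grid.

    When ``vmodels`` is not supplied, a variogram is estimated and fitted per
    attribute. The mask keeps cells within ``mask_radius`` of a sample point,
    bounding extrapolation between scanning transects.
    """
    if attrs is None:
        attrs = points.attribute_names
    mask = coverage_mask(points, geometry, mask_radius)
    layers = {}
    for attr in attrs:
        if vmodels is not None and attr in vmodels:
            vm = vmodels[attr]
        else:
            emp = empirical_semivariogram(points, attr, n_lags=n_lags, max_lag=max_lag)
            if len(emp.lag_centers) >= 3 and emp.gamma.max() > 0:
                vm = fit_variogram(emp, variogram_family)
            else:  # constant attribute: pure nugget, weights become 1/m
                vm = VariogramModel(variogram_family, 1.0, 0.0, 1.0)
        layer = ordinary_krige(points, attr, vm, geometry, neighborhood, mask)
        layers[attr] = layer.values
    return AttributeRasterStack(geometry=geometry, mask=mask, layers=layers)
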
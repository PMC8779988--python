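"""Core spatial data types and readers/writers.

Grid convention follows the ESRI ASCII standard: geometry is anchored at the
lower-left corner of the lower-left cell; array row 0 is the northernmost row
(top-down), columns run west to east.  All coordinates are projected meters.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

NODATA_DEFAULT = -9999.0
OUTLIER_LABEL = -1


@dataclass(frozen=True)
class GridGeometry:
    """Regular-grid geometry: lower-left corner, square cells, row 0 = north."""

    x0: float
    y0: float
    cell_size: float
    ncols: int
    nrows: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValidationError(f"cell_size must be > 0, got {self.cell_size}")
        if self.ncols < 1 or self.nrows < 1:
            raise ValidationError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell center coordinates as two (nrows, ncols) arrays (cx, cy)."""
        j = np.arange(self.ncols)
        i = np.arange(self.nrows)
        cx = self.x0 + (j + 0.5) * self.cell_size
        # row 0 is the top (northernmost) row
        cy = self.y0 + (self.nrows - i - 0.5) * self.cell_size
        return np.meshgrid(cx, cy)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell_size, other.cell_size)
            and self.ncols == other.ncols
            and self.nrows == other.nrows
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass
class PointSampleSet:
    """Irregular geo-referenced multi-attribute observations."""

    x: np.ndarray
    y: np.ndarray
    attributes: dict[str, np.ndarray]

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1 or len(self.x) != len(self.y):
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 1:
            raise ValidationError("point set must contain at least one point")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValidationError("coordinates must be finite")
        clean = {}
        for name, vals in self.attributes.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.x.shape:
                raise ValidationError(
                    f"attribute {name!r} has length {len(vals)}, expected {len(self.x)}"
                )
            clean[name] = vals
        self.attributes = clean

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def attribute_names(self) -> list[str]:
        return list(self.attributes)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class RasterLayer:
    """Single-attribute values on a regular grid with an in-field mask."""

    geometry: GridGeometry
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.geometry.shape or self.mask.shape != self.geometry.shape:
            raise AlignmentError("values/mask shape does not match geometry")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValidationError("values must be finite wherever mask is true")


@dataclass
class AttributeRasterStack:
    """Co-registered per-attribute layers on one grid; mask = in-field cells."""

    geometry: GridGeometry
    mask: np.ndarray
    layers: dict[str, np.ndarray]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise AlignmentError("mask shape does not match geometry")
        clean = {}
        for name, vals in self.layers.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.geometry.shape:
                raise AlignmentError(f"layer {name!r} shape does not match geometry")
            if not np.isfinite(vals[self.mask]).all():
                raise ValidationError(f"layer {name!r} has non-finite in-mask values")
            clean[name] = vals
        self.layers = clean

    @property
    def attribute_names(self) -> list[str]:
        return list(self.layers)

    def layer(self, name: str) -> RasterLayer:
        return RasterLayer(self.geometry, self.layers[name], self.mask)


@dataclass
class LabelRaster:
    """Per-cell integer cluster labels; -1 marks density-method outliers."""

    geometry: GridGeometry
    labels: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels, dtype=float)
            if np.any(lab[np.asarray(self.mask, bool)] != np.round(lab[np.asarray(self.mask, bool)])):
                raise ValidationError("labels must be integers")
            self.labels = lab.astype(int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.shape != self.geometry.shape or self.mask.shape != self.geometry.shape:
            raise AlignmentError("labels/mask shape does not match geometry")
        if (self.labels[self.mask] < OUTLIER_LABEL).any():
            raise ValidationError("labels must be >= -1 inside the mask")

    def unique_labels(self, include_outliers: bool = False) -> np.ndarray:
        vals = np.unique(self.labels[self.mask])
        if not include_outliers:
            vals = vals[vals != OUTLIER_LABEL]
        return vals


@dataclass
class FeatureMatrix:
    """Complete (no-missing) feature rows for clustering.

    ``row_index`` maps each row back to its source cell (flat index into the
    grid) or point; ``normalizers`` stores per-column (min, max) when range
    normalization has been applied, enabling the inverse mapping.
    """

    values: np.ndarray
    columns: list[str]
    row_index: np.ndarray | None = None
    normalized: bool = False
    normalizers: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.columns):
            raise ValidationError("column names do not match matrix width")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature matrix must not contain missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def read_point_table(path, x_col: str = "x", y_col: str = "y") -> PointSampleSet:
    """Read a delimited point table; all non-coordinate columns become attributes."""
    df = pd.read_csv(path)
    for col in (x_col, y_col):
        if col not in df.columns:
            raise FormatError(f"missing coordinate column {col!r}")
    attr_cols = [c for c in df.columns if c not in (x_col, y_col)]
    if not attr_cols:
        raise FormatError("no attribute columns")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"non-numeric value in column {col!r} at row {row}")
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise FormatError(f"missing value in column {col!r} at row {row}")
    return PointSampleSet(
        x=df[x_col].to_numpy(float),
        y=df[y_col].to_numpy(float),
        attributes={c: df[c].to_numpy(float) for c in attr_cols},
    )


def write_point_table(points: PointSampleSet, path, x_col: str = "x", y_col: str = "y") -> None:
    df = pd.DataFrame({x_col: points.x, y_col: points.y, **points.attributes})
    df.to_csv(path, index=False, float_format="%.10g")


_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> RasterLayer:
    """Read an ESRI ASCII grid; NODATA cells become mask = False."""
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in _ASC_HEADER_KEYS:
        if key not in header:
            raise FormatError(f"missing header keyword {key!r}")
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    geometry = GridGeometry(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size=header["cellsize"],
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
    )
    values = np.loadtxt(io.StringIO("\n".join(lines[body_start:])), ndmin=2)
    if values.shape != geometry.shape:
        raise FormatError(
            f"grid body shape {values.shape} does not match header {geometry.shape}"
        )
    mask = values != nodata
    values = np.where(mask, values, np.nan)
    return RasterLayer(geometry, values, mask)


def write_ascii_grid(layer: RasterLayer, path, nodata: float = NODATA_DEFAULT, fmt: str = "%.10g") -> None:
    g = layer.geometry
    out = np.where(layer.mask, layer.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.x0:.10g}\n")
        fh.write(f"yllcorner {g.y0:.10g}\n")
        fh.write(f"cellsize {g.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, out, fmt=fmt)


def read_label_grid(path) -> LabelRaster:
    layer = read_ascii_grid(path)
    labels = np.where(layer.mask, layer.values, OUTLIER_LABEL)
    return LabelRaster(layer.geometry, labels.astype(int), layer.mask)


def write_label_grid(labels: LabelRaster, path, nodata: int = -9999) -> None:
    layer = RasterLayer(labels.geometry, labels.labels.astype(float), labels.mask)
    write_ascii_grid(layer, path, nodata=nodata, fmt="%d")


def stack_layers(layers: dict[str, RasterLayer]) -> AttributeRasterStack:
    """Combine single-attribute layers; the stack mask is the conjunction of masks."""
    if not layers:
        raise ValidationError("no layers to stack")
    names = list(layers)
    geometry = layers[names[0]].geometry
    for name in names[1:]:
        if layers[name].geometry != geometry:
            raise AlignmentError(f"layer {name!r} geometry differs from {names[0]!r}")
    mask = np.logical_and.reduce([layers[n].mask for n in names])
    if not mask.any():
        warnings.warn("stacked mask is empty: no cell is valid in every layer")
    return AttributeRasterStack(
        geometry=geometry,
        mask=mask,
        layers={n: np.where(mask, layers[n].values, np.nan) for n in names},
    )
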
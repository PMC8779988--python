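"""End-to-end orchestration: kriging -> normalization -> feature selection ->
clustering -> smoothing, plus the multi-scenario evaluation runner.

The default recipe is k-means with k=4 on normalized, feature-decreased
attributes without coordinates, followed by island smoothing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clustering as cl
from .data_model import (
    AttributeRasterStack,
    GridGeometry,
    LabelRaster,
    PointSampleSet,
    read_ascii_grid,
    read_point_table,
    stack_layers,
    write_label_grid,
)
from .errors import ValidationError
from .kriging import points_to_stack
from .preprocessing import ScenarioSpec, build_feature_matrix, standard_scenarios
from .smoothing import SmoothingSpec, smooth
from .synthetic import FieldSimSpec, generate_field, score_recovery
from .validity import ValidityReport, evaluate_labeling, evaluate_scenarios


@dataclass
class PipelineConfig:
    """All knobs of one run; constructed from a plain dict / YAML file."""

    scenario: str = "kmeans-nc-dec"
    k: int = 4
    seed: int = 0
    selection_priority: list[str] | None = None
    selection_threshold: float = 0.7
    cell_size: float = 5.0
    mask_radius: float = 24.0
    variogram_family: str = "spherical"
    variogram_n_lags: int = 15
    variogram_max_lag: float | None = None
    kriging_neighborhood: int = 32
    fcm_m: float = 2.0
    meanshift_quantile: float = 0.3
    meanshift_h: float | None = None
    dbscan_eps: float | None = None
    dbscan_min_pts: int = 3
    smoothing_island_size: int = 5
    smoothing_eps: float | None = None
    smoothing_min_pts: int = 3
    smoothing_max_passes: int = 20
    linkage: str = "single"
    n_restarts: int = 10
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        ScenarioSpec.from_name(cfg.scenario)  # validate the name grammar
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class CaspResult:
    raw_labels: LabelRaster
    smoothed_labels: LabelRaster
    validity: ValidityReport
    selection: object | None
    audit: list
    log: list[dict] = field(default_factory=list)


def labels_to_raster(labels: np.ndarray, row_index: np.ndarray,
                     geometry: GridGeometry) -> LabelRaster:
    """Scatter per-row labels back onto the grid via the row -> cell index."""
    grid = np.full(geometry.nrows * geometry.ncols, -1, dtype=int)
    mask = np.zeros(geometry.nrows * geometry.ncols, dtype=bool)
    grid[row_index] = labels
    mask[row_index] = True
    return LabelRaster(geometry, grid.reshape(geometry.shape),
                       mask.reshape(geometry.shape))


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def krige_stage(points: PointSampleSet, config: PipelineConfig,
                geometry: GridGeometry | None = None) -> AttributeRasterStack:
    if geometry is None:
        cs = config.cell_size
        x0 = np.floor(points.x.min() / cs) * cs
        y0 = np.floor(points.y.min() / cs) * cs
        ncols = int(np.ceil((points.x.max() - x0) / cs)) + 1
        nrows = int(np.ceil((points.y.max() - y0) / cs)) + 1
        geometry = GridGeometry(x0, y0, cs, ncols, nrows)
    return points_to_stack(
        points, geometry,
        neighborhood=config.kriging_neighborhood,
        mask_radius=config.mask_radius,
        variogram_family=config.variogram_family,
        n_lags=config.variogram_n_lags,
        max_lag=config.variogram_max_lag,
    )


def run_casp(config: PipelineConfig,
             stack: AttributeRasterStack | None = None,
             points: PointSampleSet | None = None,
             grid: GridGeometry | None = None) -> CaspResult:
    """Run the full pipeline on either a point set (kriged first) or a stack.

    Stages in order: kriging (points input only), range normalization, feature
    selection, clustering, island smoothing.  Every stage appends a log record
    with input/output digests so the run is reproducible from config + seed.
    """
    if (stack is None) == (points is None):
        raise ValidationError("provide exactly one of stack or points")
    log: list[dict] = []
    if points is not None:
        stack = krige_stage(points, config, grid)
        log.append({"stage": "kriging", "n_points": points.n,
                    "grid": list(stack.geometry.shape),
                    "out": _digest(np.nan_to_num(np.array(list(stack.layers.values()))))})
    scenario = ScenarioSpec.from_name(config.scenario)
    matrix, selection = build_feature_matrix(
        stack, scenario, config.selection_priority, config.selection_threshold
    )
    log.append({
        "stage": "features", "scenario": scenario.name,
        "columns": matrix.columns, "normalized": matrix.normalized,
        "removed": selection.removed if selection else [],
        "out": _digest(matrix.values),
    })
    ms_spec = (cl.MeanShiftSpec(h=config.meanshift_h)
               if config.meanshift_h else None)
    db_spec = (cl.DBSCANSpec(eps=config.dbscan_eps, min_pts=config.dbscan_min_pts)
               if config.dbscan_eps else None)
    model = cl.run_algorithm(
        matrix, scenario.algorithm, k=config.k, seed=config.seed,
        fcm_m=config.fcm_m, meanshift_spec=ms_spec,
        meanshift_quantile=config.meanshift_quantile,
        dbscan_spec=db_spec, linkage=config.linkage,
        n_restarts=config.n_restarts,
    )
    raw_labels = labels_to_raster(model.labels, matrix.row_index, stack.geometry)
    log.append({"stage": "clustering", "algorithm": scenario.algorithm,
                "k": model.k, "seed": config.seed, "out": _digest(model.labels)})
    raw_values = {a: stack.layers[a][stack.mask] for a in stack.attribute_names}
    validity = evaluate_labeling(matrix, model.labels, raw_values)
    sspec = SmoothingSpec(
        island_size=config.smoothing_island_size, eps=config.smoothing_eps,
        min_pts=config.smoothing_min_pts, max_passes=config.smoothing_max_passes,
    )
    smoothed, audit = smooth(raw_labels, sspec)
    log.append({"stage": "smoothing", "island_size": sspec.island_size,
                "n_islands": len(audit), "out": _digest(smoothed.labels)})
    result = CaspResult(raw_labels=raw_labels, smoothed_labels=smoothed,
                        validity=validity, selection=selection, audit=audit, log=log)
    if config.output_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: CaspResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_label_grid(result.raw_labels, out / "labels_raw.asc")
    write_label_grid(result.smoothed_labels, out / "labels_smoothed.asc")
    with open(out / "run_log.json", "w") as fh:
        json.dump({"config": asdict(config), "log": result.log,
                   "validity": result.validity.as_row()}, fh, indent=2, default=str)


def run_scenarios(config: PipelineConfig, stack: AttributeRasterStack,
                  scenarios: list[ScenarioSpec] | None = None) -> list[dict]:
    """Evaluate a scenario grid (default: the standard 21) on one stack."""
    if scenarios is None:
        scenarios = standard_scenarios()
    eval_cfg = {
        "k": config.k, "seed": config.seed,
        "priority": config.selection_priority,
        "threshold": config.selection_threshold,
        "fcm_m": config.fcm_m,
        "meanshift_quantile": config.meanshift_quantile,
        "meanshift_h": config.meanshift_h,
        "dbscan_eps": config.dbscan_eps if config.dbscan_eps else 0.5,
        "dbscan_min_pts": config.dbscan_min_pts,
        "linkage": config.linkage,
        "n_restarts": config.n_restarts,
    }
    return evaluate_scenarios(stack, scenarios, eval_cfg)


def recovery_experiment(spec: FieldSimSpec, config: PipelineConfig,
                        from_points: bool = True) -> dict:
    """Generate a synthetic field, run the pipeline, score against truth.

    Returns adjusted Rand index of the raw (pre-smoothing) labeling against
    the true zones, plus the validity report.
    """
    fld = generate_field(spec)
    if from_points:
        result = run_casp(config, points=fld.samples, grid=fld.stack.geometry)
    else:
        result = run_casp(config, stack=fld.stack)
    ari = score_recovery(fld.truth, result.raw_labels)
    ari_smoothed = score_recovery(fld.truth, result.smoothed_labels)
    return {"ari": ari, "ari_smoothed": ari_smoothed,
            "validity": result.validity, "result": result, "field": fld}


def load_stack_from_grids(paths: dict[str, str]) -> AttributeRasterStack:
    return stack_layers({name: read_ascii_grid(p) for name, p in paths.items()})


def load_points(path, x_col: str = "x", y_col: str = "y") -> PointSampleSet:
    return read_point_table(path, x_col, y_col)
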
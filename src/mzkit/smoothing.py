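"""Island smoothing of label rasters.

Small disconnected fragments of a cluster ("islands") embedded in another
cluster are detected by running spatial DBSCAN on the cell centers of each
cluster, and re-labeled by a majority vote of the outside neighbors of their
edge cells.  With the default eps = cell_size * sqrt(2) (+ tolerance) the
DBSCAN step is exactly 8-connectivity on the grid.  Passes repeat until a
fixed point (re-labeling can create new sub-threshold fragments) or the pass
cap is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .clustering import DBSCANSpec, dbscan
from .data_model import LabelRaster
from .errors import ValidationError

OUTLIER = -1


@dataclass
class SmoothingSpec:
    island_size: int            # components smaller than this are re-labeled
    eps: float | None = None    # spatial DBSCAN radius, meters; default cell diag
    min_pts: int = 3
    max_passes: int = 20
    neighbor_radius: float | None = None  # edge-vote radius; default = eps

    def __post_init__(self):
        if self.island_size < 1:
            raise ValidationError("island_size must be >= 1")
        if self.eps is not None and self.eps <= 0:
            raise ValidationError("eps must be > 0")
        if self.min_pts < 1:
            raise ValidationError("min_pts must be >= 1")

    def resolved(self, cell_size: float) -> "SmoothingSpec":
        eps = self.eps if self.eps is not None else cell_size * np.sqrt(2) + 1e-6
        nr = self.neighbor_radius if self.neighbor_radius is not None else eps
        return SmoothingSpec(self.island_size, eps, self.min_pts, self.max_passes, nr)


@dataclass
class IslandRecord:
    cluster_label: int
    component_id: int
    member_cells: np.ndarray    # flat cell indices
    size: int
    edge_cells: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    vote_tally: dict[int, int] = field(default_factory=dict)
    assigned_label: int | None = None
    pass_number: int = 0


def _cell_coords(labels: LabelRaster) -> np.ndarray:
    cx, cy = labels.geometry.cell_centers()
    return np.column_stack([cx.ravel(), cy.ravel()])


def find_components(labels: LabelRaster, cluster_label: int, eps: float,
                    min_pts: int = 3) -> tuple[list[np.ndarray], np.ndarray]:
    """Spatial DBSCAN over the cells of one cluster.

    Returns (components, outlier_cells); each component is an array of flat
    cell indices, outlier_cells are DBSCAN noise cells of that cluster.
    """
    flat_idx = np.flatnonzero((labels.labels == cluster_label).ravel() & labels.mask.ravel())
    if len(flat_idx) == 0:
        raise ValidationError(f"cluster {cluster_label} has no cells")
    coords = _cell_coords(labels)[flat_idx]
    model = dbscan(coords, DBSCANSpec(eps=eps, min_pts=min_pts))
    components = [flat_idx[model.labels == c] for c in range(model.k)]
    outliers = flat_idx[model.labels == OUTLIER]
    return components, outliers


def reassign_outliers(labels: LabelRaster, outlier_cells: np.ndarray) -> LabelRaster:
    """Each outlier cell takes the label of its nearest non-outlier in-mask
    cell (Euclidean on centers; ties -> lowest label)."""
    if len(outlier_cells) == 0:
        return labels
    lab = labels.labels.copy()
    flat_mask = labels.mask.ravel()
    coords = _cell_coords(labels)
    is_outlier = np.zeros(lab.size, dtype=bool)
    is_outlier[outlier_cells] = True
    donor_idx = np.flatnonzero(flat_mask & ~is_outlier)
    if len(donor_idx) == 0:
        raise ValidationError("no non-outlier cells to reassign from")
    tree = cKDTree(coords[donor_idx])
    dist, nearest = tree.query(coords[outlier_cells], k=min(len(donor_idx), 8))
    dist = np.atleast_2d(dist)
    nearest = np.atleast_2d(nearest)
    lab_flat = lab.ravel()
    for row, cell in enumerate(outlier_cells):
        tied = np.isclose(dist[row], dist[row, 0], rtol=0.0, atol=1e-9)
        candidates = lab_flat[donor_idx[nearest[row][tied]]]
        lab_flat[cell] = candidates.min()  # tie -> lowest label
    return LabelRaster(labels.geometry, lab_flat.reshape(lab.shape), labels.mask)


def _edge_votes(labels: LabelRaster, member_cells: np.ndarray,
                neighbor_radius: float) -> tuple[np.ndarray, dict[int, int]]:
    """Edge cells of an island and the multiplicity-weighted votes of their
    outside in-mask neighbors."""
    coords = _cell_coords(labels)
    flat_mask = labels.mask.ravel()
    lab_flat = labels.labels.ravel()
    in_island = np.zeros(lab_flat.size, dtype=bool)
    in_island[member_cells] = True
    outside_idx = np.flatnonzero(flat_mask & ~in_island)
    if len(outside_idx) == 0:
        return np.empty(0, int), {}
    tree = cKDTree(coords[outside_idx])
    edge = []
    tally: dict[int, int] = {}
    for cell in member_cells:
        nb = tree.query_ball_point(coords[cell], neighbor_radius)
        if nb:
            edge.append(cell)
            for j in nb:
                v = int(lab_flat[outside_idx[j]])
                tally[v] = tally.get(v, 0) + 1
    return np.asarray(edge, int), tally


def relabel_island(labels: LabelRaster, island: IslandRecord,
                   neighbor_radius: float) -> tuple[LabelRaster, IslandRecord]:
    """Re-label an entire island to the plurality label of the outside
    neighbors of its edge cells (votes counted with multiplicity; ties ->
    lowest label)."""
    edge, tally = _edge_votes(labels, island.member_cells, neighbor_radius)
    island.edge_cells = edge
    island.vote_tally = tally
    if not tally:
        warnings.warn("island has no outside neighbors; left unchanged")
        return labels, island
    best = max(tally.values())
    winner = min(lab for lab, cnt in tally.items() if cnt == best)
    island.assigned_label = winner
    lab = labels.labels.copy()
    lab.ravel()[island.member_cells] = winner
    return LabelRaster(labels.geometry, lab, labels.mask), island


def smooth(labels: LabelRaster, spec: SmoothingSpec
           ) -> tuple[LabelRaster, list[IslandRecord]]:
    """Iterated island removal until no sub-threshold component remains.

    Per pass, clusters are visited in ascending label order: their spatial
    components are found, DBSCAN-noise cells join their nearest neighbor's
    cluster, and every component smaller than ``island_size`` is re-labeled by
    edge-neighbor majority.  Returns the smoothed raster and the audit trail.
    """
    spec = spec.resolved(labels.geometry.cell_size)
    current = LabelRaster(labels.geometry, labels.labels.copy(), labels.mask)
    audit: list[IslandRecord] = []
    for pass_no in range(1, spec.max_passes + 1):
        changed = False
        for cluster_label in current.unique_labels().tolist():
            if not (current.labels == cluster_label)[current.mask].any():
                continue  # emptied earlier this pass
            components, outliers = find_components(
                current, cluster_label, spec.eps, spec.min_pts
            )
            if len(outliers):
                before = current.labels.ravel()[outliers].copy()
                current = reassign_outliers(current, outliers)
                after = current.labels.ravel()[outliers]
                moved = outliers[after != before]
                if len(moved):
                    # audit entry: component_id -1 marks outlier reassignment
                    audit.append(IslandRecord(
                        cluster_label=cluster_label, component_id=-1,
                        member_cells=moved, size=len(moved),
                        pass_number=pass_no,
                    ))
                    changed = True
            for comp_id, comp in enumerate(components):
                if len(comp) >= spec.island_size:
                    continue
                record = IslandRecord(
                    cluster_label=cluster_label,
                    component_id=comp_id,
                    member_cells=comp,
                    size=len(comp),
                    pass_number=pass_no,
                )
                current, record = relabel_island(current, record, spec.neighbor_radius)
                if record.assigned_label is not None:
                    audit.append(record)
                    changed = True
        if not changed:
            break
    else:
        warnings.warn(f"smoothing did not converge within {spec.max_passes} passes")
    return current, audit


def flood_fill_components(labels: LabelRaster) -> list[tuple[int, np.ndarray]]:
    """8-connected components per label (independent of the DBSCAN route);
    used as the post-condition verifier."""
    from scipy import ndimage

    out = []
    structure = np.ones((3, 3), dtype=bool)
    for lab in labels.unique_labels(include_outliers=True).tolist():
        sel = (labels.labels == lab) & labels.mask
        comp, n = ndimage.label(sel, structure=structure)
        for c in range(1, n + 1):
            out.append((lab, np.flatnonzero((comp == c).ravel())))
    return out


def min_component_size(labels: LabelRaster) -> int:
    comps = flood_fill_components(labels)
    return min(len(cells) for _, cells in comps) if comps else 0
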
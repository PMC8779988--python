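# mzkit

Management-zone delineation from high-resolution proximal/remote soil and
crop data. The package covers the full clustering-and-smoothing workflow:

1. **Kriging** — semivariogram estimation, weighted least-squares model
   fitting (spherical / exponential / gaussian), and ordinary kriging of each
   attribute from irregular scan points onto a common regular grid (default
   5 × 5 m).
2. **Preprocessing** — range normalization to [0, 1] and greedy
   priority-ordered feature selection that drops attributes whose |Pearson r|
   against an already-kept attribute exceeds a threshold (default 0.7).
3. **Clustering** — five algorithms implemented in-package: k-means (Lloyd +
   single-point refinement, restarts), fuzzy C-means, mean shift, agglomerative
   hierarchical (single/complete/average/ward), and DBSCAN (label −1 marks
   outliers).
4. **Validity scoring** — Davies–Bouldin index, Silhouette index, and the
   variance reduction index (VRI, computed on raw attribute rasters with
   population variances); fewer than two clusters reports "n.v." and VRI 0.
5. **Smoothing** — spatial-DBSCAN island detection per cluster, outlier
   reassignment to the nearest cell, and majority-rule relabeling of
   components smaller than a machinery-driven `island_size`, iterated to a
   fixed point.
6. **Synthetic fields** — seeded Voronoi/banded zone maps, Gaussian random
   fields by circulant embedding, cross-correlated attributes, and transect
   sampling (dense along lines, 12 m line spacing), so every stage is testable
   without field data.

The end-to-end recipe (`run_casp`) runs: kriging (for point input) → range
normalization → feature selection → k-means (k = 4 by default) → smoothing.
A 21-scenario evaluation grid (`run_scenarios`) sweeps all five algorithms ×
input formats (normalization on/off, coordinates on/off, feature decrease
on/off) and reports DBI / Silhouette / VRI per scenario.

## CLI

All functionality is exposed through the `mzkit` entry point:

```sh
mzkit simulate --seed 3 --out-dir sim/                 # synthetic field
mzkit krige --points sim/samples.csv --out-dir grids/  # points -> rasters
mzkit cluster --grids grids/attr0.asc --grids grids/attr1.asc --out labels.asc
mzkit evaluate --grids grids/attr0.asc --grids grids/attr1.asc --labels labels.asc
mzkit smooth --labels labels.asc --island-size 5 --out smoothed.asc --audit audit.csv
mzkit casp --grids grids/attr0.asc --grids grids/attr1.asc --out-dir run/   # end to end
mzkit scenarios --grids grids/attr0.asc --grids grids/attr1.asc --out report.csv
```

Options can also come from a YAML config (`--config cfg.yaml`) whose keys
mirror `mzkit.pipeline.PipelineConfig` (scenario, k, seed, selection
priority/threshold, variogram/kriging settings, smoothing spec, ...).
Exit codes: 0 success, 2 validation error, 3 numeric error.

File formats are plain text throughout: CSV point tables, ESRI ASCII grids
(`.asc`) for attribute and label rasters, CSV/JSON reports.

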
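# soilkrige

Geostatistical analysis and sampling-design optimization for soil
contaminant surveys.

Urban soil monitoring programs measure potentially toxic elements (PTE —
Pb, Cu, Zn, Cr, Cd) at a few hundred fixed points and need two things from
those data: an assessment of contamination (how concentrations compare to
regional background values, and how they are structured in space) and a
defensible map of predictions for all the places that were *not* sampled.
`soilkrige` packages that workflow for environmental scientists and
monitoring-network designers:

- **Summary & enrichment** — per-element descriptive statistics (mean,
  median, SD, CV%, skewness, kurtosis) and fold enrichment of the survey
  mean over packaged regional/national background tables.
- **Autocorrelation screening** — global Moran's I (analytic
  randomization inference) and Anselin's local Moran (LISA) with
  conditional-permutation significance; significant high–low/low–high
  points are spatial outliers and can be excluded before variography.
- **Variography** — empirical semivariogram γ(h) = Σ(zᵢ−zⱼ)²/2m(h),
  weighted-least-squares fits of spherical/exponential/Gaussian models
  (nugget C0, partial sill C, range a; effective-range convention), and
  the nugget-ratio spatial-dependency classes (<25% strong, 25–75%
  moderate, >75% weak).
- **Ordinary kriging** — BLUP with Σyᵢ = 1 via Lagrange multiplier,
  ẑ(x₀) = Σyᵢz(xᵢ), on points and masked 100 m grids, with leave-one-out
  cross-validation (ME, RMSE, MSE, ASE, RMSSE) and rank-sum model
  selection.
- **Design optimization (SSA)** — spatial simulated annealing that moves
  one sample per iteration and accepts moves that lower the **mean kriging
  variance (MKV)**, a geometry-only objective, reporting the improvement
  percentage of the optimized layout.
- **Synthetic surveys** — exact Gaussian-random-field simulation of
  lognormal concentration fields with clustered/uniform/grid designs and
  ground-truth injected outliers, so every estimator is testable against
  known generating parameters.

## Worked example

```python
import numpy as np
from soilkrige import *

# seeded clustered Pb-like survey on a 12 km square
region, coords, values, _, spec, _ = canonical_survey(seed=42)

row = describe(values, "Pb")
refs = load_references()
print(f"Pb: mean {row.rounded(2)['mean']} mg/kg, CV {row.rounded(2)['cv_percent']}%")
print(f"fold over Shanghai background: {enrichment_ratios(row, refs['shanghai_background'])}")

w = build_weights(coords, zero_island_threshold(coords))
gm = global_moran(values, w)
print(f"Moran's I = {gm.I:.3f} (z = {gm.z_score:.2f}, {gm.pattern})")

log_vals = np.log(values)
model = fit_model(empirical_variogram(coords, log_vals), "spherical")
dep = classify_dependency(model)
print(f"spherical fit: C0={model.nugget:.3f}, C={model.partial_sill:.3f}, "
      f"a={model.range_m:.0f} m -> nugget ratio {dep.ratio_2dp}% ({dep.label})")

grid = krige_grid(coords, log_vals, model, region, cell_size=400.0)
print(f"initial MKV over {int(grid.mask.sum())} cells: {grid.mkv:.4f}")

res = optimize(coords, model, region,
               OptimizationConfig(n_movable=20, n_iterations=500, cell_size=400.0, seed=42))
print(f"SSA: {res.initial_mkv:.4f} -> {res.final_mkv:.4f} "
      f"({res.improvement_percent}% improvement)")
```

prints

```
Pb: mean 35.72 mg/kg, CV 32.75%
fold over Shanghai background: 1.4
Moran's I = 0.140 (z = 6.47, clustered)
spherical fit: C0=0.042, C=0.067, a=2591 m -> nugget ratio 38.64% (moderate)
initial MKV over 900 cells: 0.0967
SSA: 0.0967 -> 0.0862 (10.82% improvement)
```

Reading it: the survey mean is 1.4× the regional background (contamination
signal); values are significantly spatially clustered (z = 6.47), so
kriging is appropriate; the fitted spherical variogram has moderate spatial
dependence with a ~2.6 km range; and relocating 20 of the 120 points by SSA
lowers the mean kriging variance of the 400 m prediction grid by ~11%,
i.e. the same budget of monitoring points yields noticeably tighter
predictions everywhere.

The same workflow is scriptable from the shell:

```sh
soilkrige fixtures --outdir fx --seed 42     # survey.csv + region.geojson + config.yaml
soilkrige pipeline --config fx/config.yaml   # describe → Moran/LISA → variogram → krige → SSA → CV
soilkrige optimize --samples s.csv --element Pb --region r.geojson \
    --model model.json --movable 200 --iters 10000 --seed 42 --accept greedy
```

## Layout

```
src/soilkrige/
  synthetic.py   designs, Gaussian-field simulation, outlier injection
  summary.py     descriptive stats, enrichment/literature folds
  moran.py       distance-band weights, global/local Moran, exclusion
  variogram.py   empirical variogram, model families, WLS fitting
  kriging.py     OK point/grid prediction, MKV, LOO CV, model selection
  ssa.py         design perturbation, greedy/annealing optimization
  io.py          sample CSV, GeoJSON regions, ESRI ASCII grids
  pipeline.py    end-to-end YAML-configured analysis
  cli.py         `soilkrige` command-line interface
docs/methods.md  model conventions, numerical choices, limitations
```

See `docs/methods.md` for conventions that matter when comparing against
other software (effective-range factor, weights styles, scales).
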
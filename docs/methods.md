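# Methods

`soilkrige` implements the geostatistical workflow used to audit and
optimize soil-contaminant monitoring networks: descriptive and enrichment
statistics, spatial-autocorrelation screening, semivariogram modelling,
ordinary kriging with cross-validation, and spatial simulated annealing
(SSA) over the sampling layout with the mean kriging variance (MKV) as the
design objective. This note records the models, the conventions, and the
choices made where the design was genuinely open.

## Data model and scales

A survey is a set of point observations (planar metre coordinates, one
concentration in mg kg⁻¹ per element). Concentrations of trace metals in
urban soils are right-skewed and well described by lognormal marginals, so
all variography, kriging and design optimization operate on
log-concentrations; descriptive statistics and enrichment ratios operate on
the raw scale, as they are reported in surveys. MKV is therefore a variance
of log-concentration (dimensionless on the log scale). Published MKV values
quoted in mg kg⁻¹ are treated as inputs to the improvement-percentage
arithmetic only, never as absolute targets, since the reporting scale of a
variance printed in concentration units is ambiguous.

Values below an element's limit of detection (LOD) are flagged and
retained; no substitution (LOD/2 and similar) is applied. The limit of
quantification defaults to 4·LOD when only the LOD is given.

## Summary statistics

Per element: mean, median, min, max, sample standard deviation (n−1
denominator), CV% = 100·SD/mean, skewness and kurtosis. Skewness is the
bias-corrected Fisher–Pearson coefficient (G1) and kurtosis the
bias-corrected Pearson, *non-excess*, coefficient (≈3 for a normal sample);
surveys in this field typically report non-excess kurtosis, which is how
values far above 3 for contaminated soils arise. Report views round
half-up (2 dp; literature fold comparisons 1 dp); internal values keep full
precision. The CV is flagged undefined, not zeroed, when the mean is
non-positive. Background-enrichment folds are mean/background from packaged
reference tables (regional and national soil backgrounds, plus literature
city means).

## Spatial autocorrelation (Moran's I and LISA)

Weights are a fixed distance band: `j` neighbors `i` iff
0 < d(i,j) ≤ threshold, inclusive at the threshold, row-standardized by
default (binary available). Zero-neighbor points are islands: flagged,
warned about, and excluded from the statistics. When no threshold is
configured, the pipeline derives the smallest distance band leaving no
islands (the maximum nearest-neighbor distance) — the standard rule when a
band must be chosen from the data.

Global Moran's I uses the cross-product statistic on mean deviations with
expectation −1/(n−1) and the analytic randomization-assumption variance
(the permutation-moment formula involving S0, S1, S2 and the sample
kurtosis); the pattern label (clustered/dispersed/random) follows the sign
of the z-score at the chosen α with a two-sided normal p.

Local Moran's I (LISA) standardizes values by the population (1/n) standard
deviation; each point's quadrant (HH/LL/LH/HL) comes from the signs of its
own deviation and its spatial lag. Significance is by conditional
permutation (default 999 draws): the point's own value is held fixed while
the other n−1 values are permuted among its neighbors, and the one-tailed
pseudo p-value is (M+1)/(n_perm+1). Significant HH/LL points are clusters;
significant LH/HL points are spatial outliers and are the only points the
screening step removes (removal refuses to leave fewer than 10 points).

A screening limitation worth stating plainly: local Moran measures a
point's deviation against the *global* mean crossed with its neighborhood's
deviation. A contaminated spike whose neighborhood itself deviates in the
same direction is classified a significant cluster, not an outlier. For
synthetic outliers injected blindly in space with alternating
multiply/divide direction, the probability of landing in an
opposite-deviation neighborhood — the only configuration the LH/HL screen
can catch — is exactly 1/2 on any field, so the expected recall of the
screen is bounded near 0.5 times its power. The test suite freezes the
measured pooled recall of the seeded screening experiment rather than
asserting an unreachable rate; tests run the screen on log-concentrations
(variance-stabilizing, which sharpens the permutation contrast), while the
pipeline default keeps LISA on raw values to match common GIS practice.

## Semivariogram estimation and fitting

The empirical semivariogram is the method-of-moments estimator: squared
half-differences accumulated into equal-width lag bins over (0, cutoff].
Defaults: 12 lags, cutoff = half the maximum pairwise distance — the common
geostatistical rule. Bins without pairs carry no estimate.

Three bounded families are fitted: spherical, exponential, Gaussian, each
with nugget C0 ≥ 0, partial sill C ≥ 0 and range a > 0. **Range
convention:** for exponential and Gaussian the parameter is the *effective
range* (curve reaches ≈95% of the sill at h = a), i.e. the forms carry an
internal factor 3 — the convention of ArcGIS Geostatistical Analyst.
gstat-style ranges for the same curves are 3× (exponential) or √3×
(Gaussian) smaller; anyone comparing fitted ranges across software must
account for this.

Fitting is weighted least squares on the empirical variogram (not ML/REML),
with pair-count weights m_k by default or iterated Cressie weights
m_k/γ_model², box constraints (a confined to (min lag, 2·cutoff]), five
deterministic multi-starts spreading the initial range over the lag span,
best final objective winning (ties broken by smaller range, then smaller
nugget). Cressie reweighting stops as soon as the weighted objective stops
decreasing. Spatial dependency is classified from the nugget-to-sill ratio
100·C0/(C0+C): <25% strong, 25–75% moderate, >75% weak.

Only omnidirectional variograms are supported (a single range per element);
no Matérn family, no anisotropy.

## Ordinary kriging and cross-validation

The predictor solves the semivariogram-form augmented system with a
Lagrange multiplier enforcing Σy = 1; the kriging variance is
σ² = Σyᵢγ(xᵢ,x₀) + μ. The γ-form (rather than covariance form) is used
because it stays well-posed for unbounded models and yields σ² directly.
Variances in [−1e−8, 0) are clamped to zero; anything lower is an error.
With γ(0) = 0 the predictor interpolates exactly at sampled locations, with
σ² = 0 when the nugget is zero.

Neighborhoods default to *all* samples for n ≤ 500 and the nearest 32
beyond — exactness at desk scale, bounded cost at survey scale. Grid
prediction snaps the origin to integer multiples of the cell size from the
region bbox lower-left; cell-center containment (strict interior) defines
the mask; the default cell is 100 m. MKV is the arithmetic mean of the
variances over masked cells only, and — because the kriging variance
depends only on geometry and the model — is a pure function of the design.

Leave-one-out cross-validation reports ME, RMSE, MSE (mean standardized
error), ASE (mean predicted standard error) and RMSSE, the calibration
diagnostic (≈1 when predicted variances match realized errors). Family
selection ranks candidate models on RMSE↑, |ME|↑, |MSE|↑ and |RMSSE−1|↑ and
takes the smallest rank-sum, ties broken by RMSE.

## SSA design optimization

Each iteration relocates one uniformly chosen movable point by a uniform
displacement within a square whose half-width decays linearly from 10% to
1% of the region bbox diagonal over the run (no move-size rule is standard;
a decaying schedule is the usual annealing practice). Proposals are redrawn
(≤20 tries) until inside the region and ≥0.5 m from every other point, then
fall back to a uniform in-region draw. Acceptance is *greedy* by default —
a proposal is kept iff it strictly lowers the MKV — matching the
improvement-only acceptance described for this workflow; classical
annealing (Metropolis acceptance of worse moves under geometric cooling,
T0 calibrated from a short probe so roughly half of early worse moves would
be accepted) is available as an escape hatch from local minima. The movable
subset is drawn uniformly by seed. The best-ever design is returned; under
greedy acceptance the accepted-objective trace is non-increasing by
construction and asserted in tests. The objective is recomputed on the full
grid each evaluation (one factorization, many right-hand sides); no
incremental covariance update is attempted in this version.

Improvement is reported as 100·(initial − final)/initial MKV, rounded
half-up to 2 dp.

## Synthetic surveys

The generator replaces unavailable survey data with fields whose
statistical properties the analysis assumes: Gaussian random fields on the
log scale simulated *exactly* by dense Cholesky factorization of
C(h) = sill − γ(h) (diagonal jitter 1e−10·sill, escalated ×10 at most 3
times), exponentiated to lognormal concentrations; designs uniform,
gridded, or clustered (Gaussian scatters of default SD 5% of the bbox
diagonal around 6 uniform centres, mimicking the hotspot-heavy, sparse-edge
geometry of real monitoring networks); and a controlled fraction of
spatial outliers, alternately multiplied and divided by a magnitude factor,
with ground-truth indices returned for sensitivity experiments. Exact
simulation is the right trade-off below a few thousand points and keeps
parameter-recovery oracles clean. Duplicate coordinates within 0.5 m are
rejected everywhere (below plausible GPS precision; protects the kriging
solve).

The canonical fixture is a clustered 120-point Pb-like survey on a 12 km
square with the spherical log-scale model (C0=0.047, C=0.133, a=2263.3 m)
and log-mean 3.5. What the generator does **not** emulate: multi-element
cross-correlation, trends/non-stationarity, measurement-error structure
beyond the nugget, or irregular real-world region shapes. Passing tests
therefore demonstrate correctness of the estimators and the optimizer under
the stated model, not robustness to violations of it.

## Problem sizes and determinism

The test and acceptance experiments use desk-scale sizes chosen to exercise
the estimators meaningfully: 500-point surveys for variogram parameter
recovery (10 seeds; median fitted sill/range compared to the generating
model), 300-point surveys for LOO calibration (10 seeds; RMSSE within
[0.85, 1.15]), a clustered 60-point survey on a 30×30 100 m grid with 12
movable points and 300 iterations for the SSA properties, and 150-point
surveys for the outlier-screening experiment. Every random quantity flows
from explicit integer seeds; reruns are bit-reproducible.

## Known limitations

- No geographic CRS handling: coordinates are abstract planar metres.
- No universal/co-/indicator kriging; the lognormal back-transform view is
  the naive exponential (no bias correction).
- LISA-based outlier screening has the structural recall ceiling described
  above; it is a screen, not a detector of all contamination.
- WLS variogram fitting inherits the usual small-survey variance of the
  empirical variogram; short ranges relative to lag width are recovered
  with wide uncertainty.
- The SSA objective recomputation is O(n³ + n·cells) per iteration; very
  large grids or surveys call for the incremental update deliberately left
  out of this version.
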
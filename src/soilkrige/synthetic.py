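"""Synthetic spatially structured concentration surveys.

Generates the three ingredients of a soil-contaminant survey: a sampling
design inside a study region (uniform, clustered, or gridded), one
realization of a stationary Gaussian random field whose semivariance follows
a chosen variogram model (exponentiated to a lognormal marginal, as soil
trace-element concentrations typically are), and a controlled fraction of
spatial outliers with known ground-truth indices.

All operations are pure functions of (inputs, seed). The field simulator is
exact: it factorizes the dense covariance matrix C(h) = sill - gamma(h) at
the sampled locations, which is the right trade-off at survey scale
(n up to a few thousand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .constants import EPS_DUP
from .region import Region
from .variogram import VariogramModel

_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class FieldSpec:
    """What the simulated concentration field should look like.

    Attributes
    ----------
    variogram : VariogramModel
        Spatial structure on the log scale; the implied log-field variance
        is sill = C0 + C.
    log_mean : float
        Mean of log-concentration (log mg/kg).
    lognormal : bool
        If True (default), outputs are exp(gaussian field) — strictly
        positive concentrations in mg/kg. If False, the Gaussian log-scale
        field itself is returned.
    element : str
        Label, e.g. "Pb".
    """

    variogram: VariogramModel
    log_mean: float
    lognormal: bool = True
    element: str = "PTE"
    units: str = "mg kg-1"


@dataclass(frozen=True)
class SurveyConfig:
    """Sampling-design and contamination controls for a synthetic survey.

    ``cluster_sd`` defaults to 5% of the region bbox diagonal; clustered
    designs scatter points as Gaussian clouds around ``cluster_count``
    uniformly drawn centres, mimicking the hotspot clustering of real
    monitoring networks that oversample known problem areas and leave region
    edges sparse.
    """

    n_points: int
    design_mode: str = "uniform_random"
    cluster_count: int = 6
    cluster_sd: float | None = None
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.design_mode not in ("uniform_random", "clustered", "grid"):
            raise ValueError(f"unknown design_mode {self.design_mode!r}")
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if self.cluster_count < 1:
            raise ValueError("cluster_count must be >= 1")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # decorrelated per-operation streams from one survey seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _uniform_in_region(region: Region, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = region.bbox
    out = np.empty((0, 2))
    for _ in range(_MAX_REJECTION_ROUNDS):
        need = n - len(out)
        if need <= 0:
            break
        cand = np.column_stack(
            [rng.uniform(minx, maxx, 2 * need + 8), rng.uniform(miny, maxy, 2 * need + 8)]
        )
        cand = cand[region.contains_points(cand)]
        out = np.vstack([out, cand[:need]])
    if len(out) < n:
        raise RuntimeError(
            f"rejection sampling failed: placed {len(out)}/{n} points in "
            f"{_MAX_REJECTION_ROUNDS} rounds (region too small relative to its bbox?)"
        )
    return out


def sample_design(region: Region, cfg: SurveyConfig) -> np.ndarray:
    """Draw a sampling design of exactly ``cfg.n_points`` points inside region.

    Returns an (n, 2) coordinate array; reproducible for a fixed seed.
    """
    rng = _rng(cfg.seed, 1)
    n = cfg.n_points
    if cfg.design_mode == "uniform_random":
        return _uniform_in_region(region, n, rng)
    if cfg.design_mode == "grid":
        # regular lattice over the bbox, thinned evenly to exactly n points
        minx, miny, maxx, maxy = region.bbox
        k = 2
        while True:
            xs = np.linspace(minx, maxx, k + 2)[1:-1]
            ys = np.linspace(miny, maxy, k + 2)[1:-1]
            gx, gy = np.meshgrid(xs, ys)
            cand = np.column_stack([gx.ravel(), gy.ravel()])
            cand = cand[region.contains_points(cand)]
            if len(cand) >= n:
                idx = np.linspace(0, len(cand) - 1, n).round().astype(int)
                return cand[idx]
            k += max(1, k // 2)
            if k > 4096:
                raise RuntimeError("grid design failed: region admits too few lattice points")
    # clustered
    sd = cfg.cluster_sd if cfg.cluster_sd is not None else 0.05 * region.bbox_diagonal
    centers = _uniform_in_region(region, cfg.cluster_count, rng)
    assign = rng.integers(0, cfg.cluster_count, n)
    out = np.empty((n, 2))
    placed = np.zeros(n, bool)
    for _ in range(_MAX_REJECTION_ROUNDS):
        todo = np.flatnonzero(~placed)
        if todo.size == 0:
            break
        prop = centers[assign[todo]] + rng.normal(0.0, sd, (todo.size, 2))
        ok = region.contains_points(prop)
        out[todo[ok]] = prop[ok]
        placed[todo[ok]] = True
    if not placed.all():
        raise RuntimeError(
            f"clustered design failed: {int((~placed).sum())} points could not be "
            "placed inside the region within the retry budget"
        )
    return out


def simulate_field(coords: np.ndarray, spec: FieldSpec, seed: int) -> np.ndarray:
    """Draw one field realization at the given coordinates.

    A zero-mean Gaussian process with stationary covariance
    C(h) = sill - gamma(h) is sampled by Cholesky factorization of the dense
    covariance matrix, shifted by ``log_mean`` and (by default)
    exponentiated to a lognormal concentration in mg/kg.
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    n = coords.shape[0]
    if n < 1:
        raise ValueError("need at least one coordinate")
    if n > 1:
        d = pdist(coords)
        dmin = float(d.min())
        if dmin < EPS_DUP:
            full = squareform(d)
            np.fill_diagonal(full, np.inf)
            i, j = np.unravel_index(np.argmin(full), (n, n))
            raise ValueError(
                f"duplicate coordinates: points {i} and {j} are {dmin:.3g} m apart "
                f"(tolerance {EPS_DUP} m)"
            )
        dm = squareform(d)
    else:
        dm = np.zeros((1, 1))
    sill = spec.variogram.sill
    rng = np.random.default_rng(seed)
    if sill == 0.0:
        field = np.zeros(n)
    else:
        cov = spec.variogram.covariance(dm)
        np.fill_diagonal(cov, sill)  # gamma(0)=0 exactly
        jitter = 1e-10 * sill
        for attempt in range(4):
            try:
                L = np.linalg.cholesky(cov + np.eye(n) * jitter)
                break
            except np.linalg.LinAlgError:
                jitter *= 10.0
        else:  # pragma: no cover - escalation bounded above
            raise RuntimeError(
                f"covariance matrix not positive definite after jitter escalation "
                f"(min pair distance {float(dm[dm > 0].min()):.3g} m)"
            )
        field = L @ rng.standard_normal(n)
    log_vals = field + spec.log_mean
    return np.exp(log_vals) if spec.lognormal else log_vals


def inject_outliers(
    values: np.ndarray, coords: np.ndarray, cfg: SurveyConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Turn a seeded random subset of values into spatial outliers.

    Selected values are alternately multiplied and divided by
    ``outlier_magnitude``, making them stand out against their (smooth)
    neighborhood. Returns (new values, ground-truth outlier indices);
    untouched entries are bit-identical to the input.
    """
    values = np.asarray(values, float)
    n = len(values)
    k = int(round(cfg.outlier_fraction * n))
    if k == 0:
        return values.copy(), np.array([], dtype=int)
    if cfg.outlier_magnitude <= 1.0:
        raise ValueError("outlier_magnitude must be > 1 to create outliers")
    rng = _rng(cfg.seed, 2)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    out = values.copy()
    for rank, i in enumerate(idx):
        if rank % 2 == 0:
            out[i] = values[i] * cfg.outlier_magnitude
        else:
            out[i] = values[i] / cfg.outlier_magnitude
    return out, idx


def canonical_survey(
    seed: int = 42,
    n_points: int = 120,
    region_size_m: float = 12000.0,
    element: str = "Pb",
    outlier_fraction: float = 0.0,
    outlier_magnitude: float = 10.0,
    design_mode: str = "clustered",
):
    """The package's canonical seeded fixture: a clustered Pb-like survey.

    Spatial structure uses the spherical log-scale model (C0=0.047, C=0.133,
    a=2263.3 m) typical of urban lead, with log-mean 3.5 (median ~33 mg/kg)
    on a square region. Returns (region, coords, values, outlier_idx, spec,
    cfg).
    """
    region = Region.rectangle(0.0, 0.0, region_size_m, region_size_m)
    model = VariogramModel("spherical", nugget=0.047, partial_sill=0.133, range_m=2263.3)
    spec = FieldSpec(variogram=model, log_mean=3.5, lognormal=True, element=element)
    cfg = SurveyConfig(
        n_points=n_points,
        design_mode=design_mode,
        outlier_fraction=outlier_fraction,
        outlier_magnitude=outlier_magnitude,
        seed=seed,
    )
    coords = sample_design(region, cfg)
    values = simulate_field(coords, spec, seed=seed)
    values, outlier_idx = inject_outliers(values, coords, cfg)
    return region, coords, values, outlier_idx, spec, cfg
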
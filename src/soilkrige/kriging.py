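"""Ordinary kriging, masked-grid prediction, MKV, and cross-validation.

The ordinary-kriging predictor is the best linear unbiased predictor
z_hat(x0) = sum_i y_i z(x_i) with sum_i y_i = 1, obtained by solving the
semivariogram-form augmented system

    [ Gamma  1 ] [ y  ]   [ gamma0 ]
    [ 1^T    0 ] [ mu ] = [   1    ]

where Gamma_ij = gamma(|x_i - x_j|) and gamma0_i = gamma(|x_i - x0|).
The kriging variance sigma^2(x0) = sum_i y_i gamma0_i + mu depends only on
the sample geometry and the variogram model — never on the observed values
— which is what makes the mean kriging variance (MKV) over a prediction
grid usable as a pure design-quality objective.

The gamma-form system (rather than the covariance form) is used because it
remains well-posed for unbounded variogram models and yields the variance
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import rankdata

from .constants import DEFAULT_CELL_SIZE, EPS_DUP, NEG_VAR_TOL
from .region import Region
from .variogram import VariogramModel

# all-point neighborhoods up to this n; nearest-k beyond (exactness at desk
# scale, bounded cost at survey scale)
GLOBAL_NEIGHBORHOOD_MAX_N = 500
DEFAULT_NEAREST_K = 32


@dataclass(frozen=True)
class KrigingSolution:
    """Weights, Lagrange multiplier, prediction and variance at one target."""

    weights: np.ndarray
    lagrange: float
    prediction: float
    variance: float
    neighbor_idx: np.ndarray


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, float)
    if coords.shape[0] >= 2:
        if float(pdist(coords).min()) < EPS_DUP:
            raise ValueError(
                f"duplicate sample coordinates (closer than {EPS_DUP} m); kriging system singular"
            )
    return coords


def _gamma_matrix(model: VariogramModel, coords: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    G = np.zeros((n + 1, n + 1))
    if n > 1:
        G[:n, :n] = squareform(model.gamma(pdist(coords)))
    G[:n, n] = 1.0
    G[n, :n] = 1.0
    return G


def _solve_targets(
    model: VariogramModel,
    coords: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched OK solve: one factorization, many targets.

    Returns (predictions, variances, weights) with weights of shape
    (n_targets, n_samples + 1) — the last column is the Lagrange multiplier.
    """
    n = coords.shape[0]
    A = _gamma_matrix(model, coords)
    try:
        lu, piv = lu_factor(A)
    except Exception as exc:
        raise np.linalg.LinAlgError(f"singular kriging system: {exc}") from exc
    g0 = model.gamma(cdist(targets, coords))  # (m, n)
    B = np.column_stack([g0, np.ones(len(targets))])  # (m, n+1)
    X = lu_solve((lu, piv), B.T)  # (n+1, m)
    if not np.all(np.isfinite(X)):
        raise np.linalg.LinAlgError(
            "singular kriging system (degenerate variogram model or duplicate points)"
        )
    preds = values @ X[:n, :]
    variances = np.sum(B.T * X, axis=0)
    bad = variances < -NEG_VAR_TOL
    if np.any(bad):
        raise RuntimeError(
            f"kriging variance {variances[bad].min():.3g} below numerical tolerance "
            f"(-{NEG_VAR_TOL:g}); invalid variogram model?"
        )
    variances = np.maximum(variances, 0.0)
    return preds, variances, X.T


def krige_point(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    x0,
    max_neighbors: int | None = None,
) -> KrigingSolution:
    """Ordinary-kriging prediction and variance at a single target location.

    ``max_neighbors`` restricts the system to the k nearest samples;
    ``None`` uses every sample.
    """
    coords = _check_coords(coords)
    values = np.asarray(values, float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    x0 = np.asarray(x0, float).reshape(1, 2)
    if max_neighbors is not None and max_neighbors < coords.shape[0]:
        d = cdist(x0, coords)[0]
        idx = np.argsort(d)[:max_neighbors]
    else:
        idx = np.arange(coords.shape[0])
    preds, variances, X = _solve_targets(model, coords[idx], values[idx], x0)
    return KrigingSolution(
        weights=X[0, :-1],
        lagrange=float(X[0, -1]),
        prediction=float(preds[0]),
        variance=float(variances[0]),
        neighbor_idx=idx,
    )


@dataclass
class KrigingGrid:
    """Masked prediction/variance raster.

    Arrays are (n_rows, n_cols) with row 0 the northernmost row (ESRI ASCII
    order); cells outside the study region hold NaN and are excluded from
    the mask. ``mkv`` is the arithmetic mean of the kriging variances over
    masked (in-region) cells only.
    """

    xll: float
    yll: float
    cell_size: float
    predictions: np.ndarray
    variances: np.ndarray
    mask: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.predictions.shape[0]

    @property
    def n_cols(self) -> int:
        return self.predictions.shape[1]

    @property
    def mkv(self) -> float:
        return float(self.variances[self.mask].mean())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, shaped like the raster."""
        cols = self.xll + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = self.yll + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        return np.meshgrid(cols, rows)


def grid_geometry(region: Region, cell_size: float) -> tuple[float, float, int, int]:
    """Grid origin snapped to integer multiples of cell_size from the bbox
    lower-left; returns (xll, yll, n_rows, n_cols)."""
    minx, miny, maxx, maxy = region.bbox
    xll = np.floor(minx / cell_size) * cell_size
    yll = np.floor(miny / cell_size) * cell_size
    n_cols = int(np.ceil((maxx - xll) / cell_size))
    n_rows = int(np.ceil((maxy - yll) / cell_size))
    return float(xll), float(yll), n_rows, n_cols


def krige_grid(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    region: Region,
    cell_size: float = DEFAULT_CELL_SIZE,
    max_neighbors: int | str | None = "auto",
) -> KrigingGrid:
    """Predict at every grid-cell center inside the region.

    ``max_neighbors="auto"`` uses all samples when n <= 500, else the
    nearest 32. Cell-center containment defines the in-region mask; MKV is
    the mean variance over masked cells.
    """
    coords = _check_coords(coords)
    values = np.asarray(values, float)
    n = coords.shape[0]
    minx, miny, maxx, maxy = region.bbox
    sx, sy = coords[:, 0], coords[:, 1]
    if sx.max() < minx or sx.min() > maxx or sy.max() < miny or sy.min() > maxy:
        raise ValueError("region does not overlap the sample bounding box")
    xll, yll, n_rows, n_cols = grid_geometry(region, cell_size)
    xs = xll + (np.arange(n_cols) + 0.5) * cell_size
    ys = yll + (n_rows - np.arange(n_rows) - 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    mask = region.contains_points(centers).reshape(n_rows, n_cols)
    if not mask.any():
        raise ValueError("no grid-cell centers fall inside the region")

    if max_neighbors == "auto":
        max_neighbors = None if n <= GLOBAL_NEIGHBORHOOD_MAX_N else DEFAULT_NEAREST_K
    targets = centers[mask.ravel()]
    preds = np.full(n_rows * n_cols, np.nan)
    variances = np.full(n_rows * n_cols, np.nan)
    flat_idx = np.flatnonzero(mask.ravel())
    if max_neighbors is None or max_neighbors >= n:
        p, v, _ = _solve_targets(model, coords, values, targets)
        preds[flat_idx], variances[flat_idx] = p, v
    else:
        tree = cKDTree(coords)
        _, nb = tree.query(targets, k=max_neighbors)
        # group targets sharing a neighbor set to amortize factorizations
        uniq, inverse = np.unique(np.sort(nb, axis=1), axis=0, return_inverse=True)
        for u in range(len(uniq)):
            grp = np.flatnonzero(inverse == u)
            idx = uniq[u]
            p, v, _ = _solve_targets(model, coords[idx], values[idx], targets[grp])
            preds[flat_idx[grp]], variances[flat_idx[grp]] = p, v
    return KrigingGrid(
        xll=xll,
        yll=yll,
        cell_size=cell_size,
        predictions=preds.reshape(n_rows, n_cols),
        variances=variances.reshape(n_rows, n_cols),
        mask=mask,
    )


@dataclass(frozen=True)
class CrossValidationReport:
    """Leave-one-out residual diagnostics.

    me: mean error (bias); rmse: root mean square error; mse: mean
    standardized error; ase: average standard error (mean predicted sigma);
    rmsse: root mean square standardized error (~1 when the model's
    variances are well calibrated).
    """

    me: float
    rmse: float
    mse: float
    ase: float
    rmsse: float
    n: int

    def to_dict(self) -> dict:
        return {
            "me": self.me,
            "rmse": self.rmse,
            "mse": self.mse,
            "ase": self.ase,
            "rmsse": self.rmsse,
            "n": self.n,
        }


def loo_cross_validate(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    max_neighbors: int | None = None,
) -> CrossValidationReport:
    """Leave-one-out cross-validation of an ordinary-kriging model."""
    coords = _check_coords(coords)
    values = np.asarray(values, float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for cross-validation")
    preds = np.empty(n)
    sigmas = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        rest = all_idx[all_idx != i]
        sol = krige_point(coords[rest], values[rest], model, coords[i], max_neighbors)
        preds[i] = sol.prediction
        sigmas[i] = np.sqrt(sol.variance)
    if np.any(sigmas == 0):
        raise ValueError("zero kriging standard error in LOO (duplicate-point pathology?)")
    resid = preds - values
    std = resid / sigmas
    return CrossValidationReport(
        me=float(resid.mean()),
        rmse=float(np.sqrt(np.mean(resid**2))),
        mse=float(std.mean()),
        ase=float(sigmas.mean()),
        rmsse=float(np.sqrt(np.mean(std**2))),
        n=n,
    )


def select_model(candidates: list[tuple[str, CrossValidationReport]]) -> str:
    """Pick the best variogram family from LOO reports by rank-sum.

    Candidates are ranked on each of four criteria — RMSE ascending, |ME|
    ascending, |MSE| ascending, |RMSSE - 1| ascending — and the smallest
    rank-sum wins; ties break by RMSE.
    """
    if not candidates:
        raise ValueError("no candidates")
    names = [c[0] for c in candidates]
    reps = [c[1] for c in candidates]
    crit = np.array(
        [
            [r.rmse for r in reps],
            [abs(r.me) for r in reps],
            [abs(r.mse) for r in reps],
            [abs(r.rmsse - 1.0) for r in reps],
        ]
    )
    ranks = np.vstack([rankdata(row, method="average") for row in crit])
    ranksum = ranks.sum(axis=0)
    best = np.flatnonzero(ranksum == ranksum.min())
    if len(best) > 1:
        best = [best[int(np.argmin(crit[0, best]))]]
    return names[int(best[0])]
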
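"""Semivariogram estimation, theoretical models, and WLS fitting.

The empirical semivariogram is the method-of-moments estimator

    gamma(h) = 1 / (2 m(h)) * sum_{pairs at lag h} (z_i - z_j)^2

where ``m(h)`` is the number of point pairs whose separation falls in the lag
bin around ``h``. Three bounded theoretical families are supported —
spherical, exponential and Gaussian — parameterized by nugget ``C0``, partial
sill ``C`` and range ``a`` (sill = C0 + C).

Range convention
----------------
For the exponential and Gaussian families the ``a`` parameter is the
*effective* (practical) range at which the model reaches ~95% of the sill,
i.e. the curves carry an internal factor 3: ``C0 + C*(1 - exp(-3h/a))`` and
``C0 + C*(1 - exp(-3h^2/a^2))``. This is the convention used by ArcGIS
Geostatistical Analyst; gstat-style ranges for the same curve are a factor of
3 (exponential) or sqrt(3) (Gaussian) smaller.

Model fitting is weighted least squares on the empirical semivariogram with
either pair-count weights ``m_k`` or iterated Cressie weights
``m_k / gamma_model(h_k)^2``, multi-started from five deterministic initial
guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

FAMILIES = ("spherical", "gaussian", "exponential")


@dataclass(frozen=True)
class VariogramModel:
    """Bounded semivariogram model: family + nugget + partial sill + range.

    Attributes
    ----------
    family : {"spherical", "gaussian", "exponential"}
    nugget : float
        Micro-scale plus measurement-error variance C0 (>= 0).
    partial_sill : float
        Spatially structured variance C (>= 0).
    range_m : float
        (Effective) range a in metres (> 0); the lag beyond which spatial
        correlation is negligible. The spherical model reaches the sill
        exactly at ``h = range_m``.
    """

    family: str
    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}; expected one of {FAMILIES}")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.partial_sill < 0:
            raise ValueError("partial sill must be >= 0")
        if self.range_m <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h) -> np.ndarray:
        """Vectorized semivariance gamma(h); gamma(0) = 0 by convention."""
        return model_gamma(self, h)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h)."""
        return self.sill - self.gamma(h)

    def to_dict(self) -> dict:
        ratio = 100.0 * self.nugget / self.sill if self.sill > 0 else float("nan")
        return {
            "family": self.family,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "sill": self.sill,
            "range_m": self.range_m,
            "nugget_ratio_percent": ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariogramModel":
        return cls(
            family=d["family"],
            nugget=float(d["nugget"]),
            partial_sill=float(d["partial_sill"]),
            range_m=float(d["range_m"]),
        )


def model_gamma(model: VariogramModel, h) -> np.ndarray:
    """Evaluate a theoretical semivariogram at lag(s) h >= 0 (metres).

    gamma(0) = 0 exactly (the nugget is a discontinuity at the origin);
    for h > 0 the curve starts from C0 and rises to the sill.
    """
    h = np.asarray(h, dtype=float)
    scalar = h.ndim == 0
    h = np.atleast_1d(h)
    if np.any(h < 0):
        raise ValueError("lag distance h must be >= 0")
    c0, c, a = model.nugget, model.partial_sill, model.range_m
    g = np.zeros_like(h)
    pos = h > 0
    hp = h[pos]
    if model.family == "spherical":
        r = np.minimum(hp / a, 1.0)
        g[pos] = c0 + c * (1.5 * r - 0.5 * r**3)
    elif model.family == "exponential":
        g[pos] = c0 + c * (1.0 - np.exp(-3.0 * hp / a))
    else:  # gaussian
        g[pos] = c0 + c * (1.0 - np.exp(-3.0 * (hp / a) ** 2))
    return float(g[0]) if scalar else g


@dataclass
class EmpiricalVariogram:
    """Binned method-of-moments semivariogram.

    ``lags`` are bin centers (metres); bins with zero pairs carry NaN
    semivariance and are excluded from fitting.
    """

    lags: np.ndarray
    gamma: np.ndarray
    pairs: np.ndarray
    cutoff: float
    n_lags: int

    @property
    def occupied(self) -> np.ndarray:
        return self.pairs > 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lag_m": self.lags, "gamma": self.gamma, "pairs": self.pairs})


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    n_lags: int = 12,
    cutoff: float | None = None,
) -> EmpiricalVariogram:
    """Estimate the omnidirectional empirical semivariogram.

    Parameters
    ----------
    coords : (n, 2) array of planar coordinates (metres).
    values : (n,) array.
    n_lags : number of equal-width lag bins on (0, cutoff].
    cutoff : maximum pair separation considered; defaults to half the
        maximum pairwise distance.
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if coords.shape[0] != values.shape[0]:
        raise ValueError("coords and values length mismatch")
    d = pdist(coords)
    if cutoff is None:
        cutoff = 0.5 * float(d.max())
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    sqdiff = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    keep = (d > 0) & (d <= cutoff)
    if not keep.any():
        raise ValueError(f"no point pairs within cutoff {cutoff:g} m")
    d, sqdiff = d[keep], sqdiff[keep]
    width = cutoff / n_lags
    binidx = np.minimum((d / width).astype(int), n_lags - 1)
    counts = np.bincount(binidx, minlength=n_lags)
    sums = np.bincount(binidx, weights=sqdiff, minlength=n_lags)
    with np.errstate(invalid="ignore"):
        gam = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_lags) + 0.5) * width
    return EmpiricalVariogram(lags=centers, gamma=gam, pairs=counts, cutoff=cutoff, n_lags=n_lags)


def _wls_residuals(params, family, h, gam, counts, weights_mode, gamma_ref=None):
    c0, c, a = params
    m = VariogramModel(family=family, nugget=max(c0, 0.0), partial_sill=max(c, 0.0), range_m=max(a, 1e-12))
    g = model_gamma(m, h)
    if weights_mode == "pair_count":
        w = counts.astype(float)
    else:  # cressie: weights fixed at the reference model from the outer loop
        ref = g if gamma_ref is None else gamma_ref
        w = counts / np.maximum(ref, 1e-12) ** 2
    return np.sqrt(w) * (g - gam)


def fit_model(
    emp: EmpiricalVariogram,
    family: str,
    weighting: str = "pair_count",
    cressie_iterations: int = 5,
) -> VariogramModel:
    """Fit (C0, C, a) to an empirical semivariogram by bounded WLS.

    Five deterministic multi-starts spread the initial range over the lag
    span; the best final objective wins, ties broken by smaller range then
    smaller nugget. Cressie weighting (``m_k / gamma_model^2``) is iterated:
    weights are recomputed at the current fit and the fit repeated until the
    objective stops decreasing (at most ``cressie_iterations`` rounds).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if weighting not in ("pair_count", "cressie"):
        raise ValueError(f"unknown weighting {weighting!r}")
    occ = emp.occupied
    if occ.sum() < 4:
        raise ValueError(f"need >= 4 occupied lag bins, have {int(occ.sum())}")
    h, gam, counts = emp.lags[occ], emp.gamma[occ], emp.pairs[occ]

    gmax = float(gam.max())
    if gmax <= 0:
        gmax = 1e-12
    lo = np.array([0.0, 0.0, float(h.min()) * (1 + 1e-9)])
    hi = np.array([2 * gmax, 4 * gmax, 2 * emp.cutoff])
    sill0 = float(gam[-max(3, len(gam) // 4):].mean())
    nugget0 = max(min(float(gam[0]), sill0), 0.0)
    starts = []
    for frac in (0.15, 0.3, 0.5, 0.75, 1.0):
        a0 = float(np.clip(h.min() + frac * (emp.cutoff - h.min()), lo[2], hi[2]))
        c00 = 0.5 * nugget0 if frac in (0.3, 0.75) else 0.0
        c0_ = float(np.clip(c00, lo[0], hi[0]))
        cc = float(np.clip(max(sill0 - c0_, 0.1 * gmax), 1e-9, hi[1]))
        starts.append(np.array([c0_, cc, a0]))

    best = None  # (objective, range, nugget, model)
    diag = []
    for x0 in starts:
        try:
            if weighting == "pair_count":
                sol = least_squares(
                    _wls_residuals, x0, bounds=(lo, hi),
                    args=(family, h, gam, counts, "pair_count"),
                )
                obj, params = float(np.sum(sol.fun**2)), sol.x
            else:
                params = x0
                gamma_ref = None
                obj = np.inf
                for _ in range(cressie_iterations):
                    sol = least_squares(
                        _wls_residuals, params, bounds=(lo, hi),
                        args=(family, h, gam, counts, "cressie", gamma_ref),
                    )
                    params = sol.x
                    m = VariogramModel(family, max(params[0], 0), max(params[1], 0), max(params[2], 1e-12))
                    gamma_ref = model_gamma(m, h)
                    new_obj = float(
                        np.sum(counts / np.maximum(gamma_ref, 1e-12) ** 2 * (gamma_ref - gam) ** 2)
                    )
                    if new_obj >= obj - 1e-15:
                        obj = min(obj, new_obj)
                        break
                    obj = new_obj
        except Exception as exc:  # keep trying other starts
            diag.append(f"start {x0}: {exc}")
            continue
        cand = (obj, params[2], params[0], params)
        if best is None or cand[:3] < best[:3]:
            best = cand
    if best is None:
        raise RuntimeError("variogram fit failed on all starts: " + "; ".join(diag))
    c0, c, a = best[3]
    return VariogramModel(family=family, nugget=max(c0, 0.0), partial_sill=max(c, 0.0), range_m=a)


@dataclass(frozen=True)
class DependencyClass:
    """Nugget-to-sill ratio and the spatial-dependency label it implies.

    ratio < 25% -> strong; 25-75% -> moderate; > 75% -> weak spatial
    dependence.
    """

    nugget_ratio_percent: float
    label: str = field(init=False)

    def __post_init__(self):
        r = self.nugget_ratio_percent
        if r < 25.0:
            lab = "strong"
        elif r <= 75.0:
            lab = "moderate"
        else:
            lab = "weak"
        object.__setattr__(self, "label", lab)

    @property
    def ratio_2dp(self) -> float:
        from .summary import round_half_up

        return round_half_up(self.nugget_ratio_percent, 2)


def classify_dependency(model: VariogramModel) -> DependencyClass:
    """Classify spatial dependency from the nugget-to-sill ratio."""
    if model.sill <= 0:
        raise ValueError("nugget ratio undefined: C0 = C = 0")
    return DependencyClass(nugget_ratio_percent=100.0 * model.nugget / model.sill)
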
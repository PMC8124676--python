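"""Global Moran's I and Local Moran's I (LISA) spatial autocorrelation.

Distance-band spatial weights (inclusive at the threshold), the global
cross-product statistic with its analytic randomization-assumption variance,
and Anselin's local statistic with conditional-permutation significance.
Significant LH/HL points are spatial outliers — observations unlike their
surroundings — and are screened out before variography, since they distort
the empirical semivariogram.

Conventions follow GeoDa: row-standardized weights by default, local
statistics on values standardized by the population (1/n) standard
deviation, and one-tailed pseudo p-values ``(M+1)/(n_perm+1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """Fixed-distance-band neighbor structure.

    ``neighbors[i]`` holds the indices j with 0 < dist(i, j) <= threshold.
    Zero-neighbor points are islands: flagged, excluded from the statistics.
    Within a distance band each neighbor of i carries the same weight —
    1 (binary) or 1/|N(i)| (row_standardized).
    """

    neighbors: list
    style: str
    threshold: float
    n: int = field(init=False)
    island: np.ndarray = field(init=False)

    def __post_init__(self):
        self.n = len(self.neighbors)
        self.island = np.array([len(nb) == 0 for nb in self.neighbors])

    def weight(self, i: int) -> float:
        """Per-neighbor weight of row i."""
        k = len(self.neighbors[i])
        if k == 0:
            return 0.0
        return 1.0 if self.style == "binary" else 1.0 / k

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Spatial lag sum_j w_ij z_j (0 for islands)."""
        out = np.zeros(self.n)
        for i, nb in enumerate(self.neighbors):
            if len(nb):
                out[i] = self.weight(i) * z[nb].sum()
        return out

    def dense(self) -> np.ndarray:
        """Dense (n, n) weight matrix; convenience for small-n oracles."""
        W = np.zeros((self.n, self.n))
        for i, nb in enumerate(self.neighbors):
            W[i, nb] = self.weight(i)
        return W


def build_weights(
    coords: np.ndarray, threshold: float, style: str = "row_standardized"
) -> SpatialWeights:
    """Distance-band weights: j neighbors i iff 0 < dist(i,j) <= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if style not in ("binary", "row_standardized"):
        raise ValueError(f"unknown weights style {style!r}")
    coords = np.asarray(coords, float)
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    adj = d <= threshold
    neighbors = [np.flatnonzero(row) for row in adj]
    w = SpatialWeights(neighbors=neighbors, style=style, threshold=threshold)
    n_isl = int(w.island.sum())
    if n_isl == w.n:
        raise ValueError(
            f"all {w.n} points are islands at threshold {threshold:g} m; statistic undefined"
        )
    if n_isl:
        logger.warning(
            "%d island point(s) at threshold %g m excluded from Moran statistics",
            n_isl, threshold,
        )
    return w


def zero_island_threshold(coords: np.ndarray) -> float:
    """Smallest distance band leaving no point an island.

    Equals the maximum over points of the nearest-neighbor distance — the
    natural rule for choosing a distance threshold when none is prescribed.
    """
    coords = np.asarray(coords, float)
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).max())


@dataclass(frozen=True)
class GlobalMoranResult:
    I: float
    expected: float
    variance: float
    z_score: float
    p_value: float
    pattern: str

    def to_dict(self) -> dict:
        return {
            "morans_i": self.I,
            "expected": self.expected,
            "variance": self.variance,
            "z_score": self.z_score,
            "p_value": self.p_value,
            "pattern": self.pattern,
        }


def _active(values: np.ndarray, w: SpatialWeights):
    """Restrict to non-island points, reindexing the neighbor lists."""
    if not w.island.any():
        return np.asarray(values, float), w
    keep = np.flatnonzero(~w.island)
    remap = -np.ones(w.n, int)
    remap[keep] = np.arange(len(keep))
    nbs = [remap[w.neighbors[i]] for i in keep]
    sub = SpatialWeights(neighbors=[nb[nb >= 0] for nb in nbs], style=w.style, threshold=w.threshold)
    return np.asarray(values, float)[keep], sub


def global_moran(values: np.ndarray, w: SpatialWeights, alpha: float = 0.05) -> GlobalMoranResult:
    """Global Moran's I with analytic randomization-assumption inference.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the mean
    deviations; E[I] = -1/(n-1); the variance uses the standard
    randomization (permutation-moment) formula involving S0, S1, S2 and the
    sample kurtosis b2. Two-sided p from the normal approximation; pattern
    is clustered / dispersed / random by the sign of z at level alpha.
    """
    x, w = _active(values, w)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 non-island points")
    z = x - x.mean()
    m2 = float(z @ z)
    if m2 == 0.0:
        raise ValueError("values have zero variance; Moran's I undefined")

    W = w.dense()
    S0 = W.sum()
    cross = float(z @ W @ z)
    I = n / S0 * cross / m2

    S1 = 0.5 * np.sum((W + W.T) ** 2)
    rs, cs = W.sum(axis=1), W.sum(axis=0)
    S2 = np.sum((rs + cs) ** 2)
    b2 = n * np.sum(z**4) / m2**2
    EI = -1.0 / (n - 1)
    num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2) - b2 * (
        (n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * S0**2) - EI**2
    var = max(var, 0.0)
    zsc = (I - EI) / np.sqrt(var) if var > 0 else np.nan
    p = 2.0 * norm.sf(abs(zsc)) if np.isfinite(zsc) else np.nan
    if not np.isfinite(p) or p > alpha:
        pattern = "random"
    else:
        pattern = "clustered" if zsc > 0 else "dispersed"
    return GlobalMoranResult(I=I, expected=EI, variance=var, z_score=zsc, p_value=p, pattern=pattern)


@dataclass
class LocalMoranResult:
    """Per-point LISA statistics over the full input set.

    Islands get NaN statistics and role ``not_significant``. ``role`` is
    ``cluster`` for significant HH/LL, ``outlier`` for significant LH/HL.
    """

    local_i: np.ndarray
    quadrant: np.ndarray  # strings HH/LL/LH/HL ('' for islands)
    p_perm: np.ndarray
    role: np.ndarray
    alpha: float
    n_perm: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "local_i": self.local_i,
                "quadrant": self.quadrant,
                "p": self.p_perm,
                "role": self.role,
            }
        )


def local_moran(
    values: np.ndarray,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> LocalMoranResult:
    """Anselin's Local Moran's I with conditional-permutation p-values.

    Values are standardized by the population standard deviation;
    local_i[i] = z_i * lag(z)[i]. For each point the other n-1 values are
    permuted among its neighbors (``n_perm`` draws, point i held fixed) and
    the one-tailed pseudo p-value is (M+1)/(n_perm+1) where M counts
    permuted statistics at least as extreme in the observed tail.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    values = np.asarray(values, float)
    n = w.n
    if len(values) != n:
        raise ValueError("values length does not match weights")
    act = ~w.island
    x = values[act]
    if len(x) < 3:
        raise ValueError("need at least 3 non-island points")
    sd = x.std()  # population (1/n) convention
    if sd == 0:
        raise ValueError("values have zero variance; LISA undefined")
    zfull = np.full(n, np.nan)
    zfull[act] = (values[act] - x.mean()) / sd

    lag = np.full(n, np.nan)
    li = np.full(n, np.nan)
    quad = np.array([""] * n, dtype=object)
    p = np.full(n, np.nan)
    role = np.array(["not_significant"] * n, dtype=object)

    rng = np.random.default_rng(seed)
    others_pool = np.arange(n)
    for i in range(n):
        nb = w.neighbors[i]
        k = len(nb)
        if k == 0:
            continue
        wi = w.weight(i)
        lag[i] = wi * zfull[nb].sum()
        li[i] = zfull[i] * lag[i]
        quad[i] = ("H" if zfull[i] > 0 else "L") + ("H" if lag[i] > 0 else "L")
        # conditional permutation: draw k of the other n-1 values, n_perm times
        pool = zfull[np.concatenate([others_pool[:i], others_pool[i + 1:]])]
        pool = pool[np.isfinite(pool)]
        keys = rng.random((n_perm, len(pool)))
        pick = np.argpartition(keys, k - 1, axis=1)[:, :k]
        perm_stat = zfull[i] * wi * pool[pick].sum(axis=1)
        if li[i] >= 0:
            M = int(np.sum(perm_stat >= li[i]))
        else:
            M = int(np.sum(perm_stat <= li[i]))
        p[i] = (M + 1) / (n_perm + 1)
        if p[i] <= alpha:
            role[i] = "cluster" if quad[i] in ("HH", "LL") else "outlier"
    return LocalMoranResult(
        local_i=li, quadrant=quad, p_perm=p, role=role, alpha=alpha, n_perm=n_perm
    )


def exclude_outliers(
    coords: np.ndarray,
    values: np.ndarray,
    lisa: LocalMoranResult,
    alpha: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop points flagged as significant spatial outliers (LH/HL).

    ``alpha`` defaults to the level the LISA was computed at; a stricter
    level may be passed (points with p_perm <= alpha in LH/HL quadrants are
    removed). Survivor order is preserved. Returns
    (coords_kept, values_kept, removed_indices).
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    if len(values) != len(lisa.local_i):
        raise ValueError("LISA result does not match the sample set")
    if alpha is None:
        alpha = lisa.alpha
    is_out = np.array(
        [
            q in ("LH", "HL") and np.isfinite(pp) and pp <= alpha and alpha > 0
            for q, pp in zip(lisa.quadrant, lisa.p_perm)
        ]
    )
    removed = np.flatnonzero(is_out)
    if len(values) - len(removed) < 10:
        raise ValueError(
            f"outlier removal would leave {len(values) - len(removed)} points (< 10); "
            "downstream variography unreliable"
        )
    if len(removed):
        logger.info("excluded %d spatial outlier(s) at alpha=%g", len(removed), alpha)
    keep = ~is_out
    return coords[keep], values[keep], removed
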
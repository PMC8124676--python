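"""Spatial simulated annealing (SSA) optimization of a sampling layout.

Each iteration relocates one randomly chosen movable sample point and
re-evaluates the mean kriging variance (MKV) over the prediction grid.
Because the kriging variance depends only on sample geometry and the
variogram model, MKV is a pure design objective: lowering it spreads the
network into under-sampled areas and tightens predictions everywhere.

Two acceptance rules are provided: ``greedy`` (improvement-only — a move is
kept iff it lowers the MKV) and ``annealing`` (Metropolis acceptance of
worse moves with probability exp(-delta/T) under geometric cooling), the
classical escape hatch from local minima. Proposal step sizes shrink over
the run from 10% to 1% of the region bbox diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import DEFAULT_CELL_SIZE, EPS_DUP
from .kriging import krige_grid
from .region import Region
from .synthetic import _uniform_in_region
from .variogram import VariogramModel


@dataclass
class Design:
    """A sampling layout split into fixed and movable points.

    ``movable_idx`` indexes rows of ``coords``; every point must lie inside
    the region and no two points may be closer than the duplicate tolerance.
    """

    coords: np.ndarray
    movable_idx: np.ndarray
    region: Region

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.movable_idx = np.asarray(self.movable_idx, int)
        n = len(self.coords)
        if len(np.unique(self.movable_idx)) != len(self.movable_idx):
            raise ValueError("movable_idx contains duplicates")
        if self.movable_idx.size and (self.movable_idx.min() < 0 or self.movable_idx.max() >= n):
            raise ValueError("movable_idx out of bounds")
        if not self.region.contains_points(self.coords).all():
            raise ValueError("design contains points outside the region")
        if n >= 2:
            d = cdist(self.coords, self.coords)
            np.fill_diagonal(d, np.inf)
            if d.min() < EPS_DUP:
                raise ValueError(f"design contains points closer than {EPS_DUP} m")

    def replaced(self, i: int, xy: np.ndarray) -> "Design":
        new = self.coords.copy()
        new[i] = xy
        obj = Design.__new__(Design)  # skip re-validation; caller guarantees legality
        obj.coords = new
        obj.movable_idx = self.movable_idx
        obj.region = self.region
        return obj


@dataclass(frozen=True)
class OptimizationConfig:
    """SSA run controls.

    ``n_movable`` points are drawn from the survey by seed (the typical
    experiment sweeps 50-200); ``n_iterations`` defaults to 10,000. The
    jitter schedule decays linearly from ``jitter_start`` to ``jitter_end``
    (fractions of the bbox diagonal). ``initial_temperature=None`` under
    annealing calibrates T0 from a short probe so that about half of early
    worse moves would be accepted.
    """

    n_movable: int
    n_iterations: int = 10_000
    acceptance: str = "greedy"
    initial_temperature: float | None = None
    cooling_factor: float = 0.999
    jitter_start: float = 0.10
    jitter_end: float = 0.01
    cell_size: float = DEFAULT_CELL_SIZE
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.acceptance not in ("greedy", "annealing"):
            raise ValueError(f"unknown acceptance rule {self.acceptance!r}")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must be in (0, 1)")

    def jitter_fraction(self, step: int) -> float:
        t = step / max(self.n_iterations - 1, 1)
        return self.jitter_start + t * (self.jitter_end - self.jitter_start)


@dataclass
class OptimizationResult:
    """Trajectory and outcome of one SSA run."""

    initial_mkv: float
    final_mkv: float
    design: Design
    trace: list = field(repr=False)  # (iteration, proposed_mkv, accepted)
    improvement: float = field(init=False)

    def __post_init__(self):
        self.improvement = improvement_percent(self.initial_mkv, self.final_mkv, rounded=False)

    @property
    def improvement_percent(self) -> float:
        return improvement_percent(self.initial_mkv, self.final_mkv)

    def accepted_trace(self) -> np.ndarray:
        """Objective value after each iteration (current design's MKV)."""
        out = np.empty(len(self.trace))
        cur = self.initial_mkv
        for k, (_, prop, acc) in enumerate(self.trace):
            if acc:
                cur = prop
            out[k] = cur
        return out

    def to_dict(self) -> dict:
        return {
            "initial_mkv": self.initial_mkv,
            "final_mkv": self.final_mkv,
            "improvement_percent": self.improvement_percent,
            "n_iterations": len(self.trace),
            "n_accepted": int(sum(acc for _, _, acc in self.trace)),
        }


def objective_mkv(
    design: Design, model: VariogramModel, cell_size: float = DEFAULT_CELL_SIZE
) -> float:
    """MKV of a design: mean kriging variance over the in-region grid.

    Observed values are irrelevant (the kriging variance is geometry-only),
    so a dummy value vector is kriged.
    """
    grid = krige_grid(
        design.coords,
        np.zeros(len(design.coords)),
        model,
        design.region,
        cell_size=cell_size,
    )
    return grid.mkv


def perturb(
    design: Design, rng: np.random.Generator, step: int, cfg: OptimizationConfig
) -> Design:
    """Propose a design differing in exactly one movable point's location.

    The new location is the current one plus a uniform displacement within a
    square of half-width jitter_fraction(step) * bbox diagonal, re-proposed
    (up to 20 tries) until it is inside the region and at least the
    duplicate tolerance from all other points; after 20 failures a uniform
    in-region draw is used as fallback.
    """
    if design.movable_idx.size == 0:
        raise ValueError("design has no movable points")
    i = int(design.movable_idx[rng.integers(len(design.movable_idx))])
    half = cfg.jitter_fraction(step) * design.region.bbox_diagonal
    others = np.delete(design.coords, i, axis=0)
    for attempt in range(20):
        xy = design.coords[i] + rng.uniform(-half, half, 2)
        if design.region.contains(xy[0], xy[1]) and (
            cdist(xy[None, :], others).min() >= EPS_DUP
        ):
            return design.replaced(i, xy)
    for attempt in range(20):
        xy = _uniform_in_region(design.region, 1, rng)[0]
        if cdist(xy[None, :], others).min() >= EPS_DUP:
            return design.replaced(i, xy)
    raise RuntimeError("no legal relocation found within the fallback budget")


def optimize(
    coords: np.ndarray,
    model: VariogramModel,
    region: Region,
    cfg: OptimizationConfig,
) -> OptimizationResult:
    """Run SSA over the survey layout and return the best-ever design.

    The movable subset is drawn uniformly at random from the survey by the
    config seed. Greedy acceptance keeps a proposal iff it strictly lowers
    the MKV; annealing accepts worse moves with Metropolis probability under
    geometric cooling. The trace records every proposal and its decision.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if cfg.n_movable > n:
        raise ValueError(f"n_movable={cfg.n_movable} exceeds survey size {n}")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 101]))
    movable = np.sort(rng.choice(n, size=cfg.n_movable, replace=False))
    design = Design(coords=coords.copy(), movable_idx=movable, region=region)

    current = objective_mkv(design, model, cfg.cell_size)
    initial = current
    best, best_design = current, design
    temp = cfg.initial_temperature
    if cfg.acceptance == "annealing" and temp is None:
        # probe: median worsening of a handful of early proposals -> ~50% acceptance
        probe_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 102]))
        deltas = []
        for s in range(16):
            try:
                cand = perturb(design, probe_rng, 0, cfg)
            except RuntimeError:
                continue
            dv = objective_mkv(cand, model, cfg.cell_size) - current
            if dv > 0:
                deltas.append(dv)
        temp = (np.median(deltas) / np.log(2.0)) if deltas else 1.0

    trace = []
    for step in range(cfg.n_iterations):
        proposal = perturb(design, rng, step, cfg)
        prop_mkv = objective_mkv(proposal, model, cfg.cell_size)
        delta = prop_mkv - current
        if cfg.acceptance == "greedy":
            accept = delta < 0
        else:
            accept = delta < 0 or rng.random() < np.exp(-delta / max(temp, 1e-300))
            temp *= cfg.cooling_factor
        if accept:
            design, current = proposal, prop_mkv
            if current < best:
                best, best_design = current, design
        trace.append((step, prop_mkv, bool(accept)))
    return OptimizationResult(
        initial_mkv=initial, final_mkv=best, design=best_design, trace=trace
    )


def improvement_percent(initial_mkv: float, final_mkv: float, rounded: bool = True) -> float:
    """Relative MKV reduction, 100 * (initial - final) / initial.

    Reported at 2 dp (round-half-up) by default.
    """
    if initial_mkv <= 0:
        raise ValueError("initial MKV must be > 0")
    pct = 100.0 * (initial_mkv - final_mkv) / initial_mkv
    if rounded:
        from .summary import round_half_up

        return round_half_up(pct, 2)
    return pct
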
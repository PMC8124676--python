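"""Descriptive statistics and background-enrichment comparisons.

Summarizes per-element concentration vectors (mean, median, range, SD, CV%,
skewness, kurtosis) and compares survey means against reference tables:
regional/national soil background values (fold enrichment, 2 dp) and
literature means from other cities (fold comparison, 1 dp).

Conventions: SD is the sample (n-1) standard deviation; CV% = 100*SD/mean;
skewness is the bias-corrected Fisher-Pearson coefficient and kurtosis the
bias-corrected Pearson (non-excess) coefficient, so a normal sample has
kurtosis ~3. Report views round half-up; internal values keep full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import numpy as np
import yaml
from scipy import stats


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics for one element (mg/kg; CV/skew/kurt unitless).

    ``cv_percent`` is NaN with ``cv_defined=False`` when the mean is
    non-positive (the CV is then meaningless, never silently zeroed).
    """

    element: str
    n: int
    mean: float
    median: float
    min: float
    max: float
    sd: float
    cv_percent: float
    skewness: float
    kurtosis: float
    cv_defined: bool = True

    def rounded(self, ndigits: int = 2) -> dict:
        out = {"element": self.element, "n": self.n}
        for k in ("mean", "median", "min", "max", "sd", "cv_percent", "skewness", "kurtosis"):
            v = getattr(self, k)
            out[k] = round_half_up(v, ndigits) if np.isfinite(v) else float("nan")
        return out


@dataclass(frozen=True)
class ReferenceTable:
    """Named element -> concentration (mg/kg) lookup, e.g. a soil background."""

    source: str
    values: dict

    def __post_init__(self):
        for el, v in self.values.items():
            if not (v > 0):
                raise ValueError(f"reference value for {el} must be > 0, got {v}")

    def __getitem__(self, element: str) -> float:
        if element not in self.values:
            raise KeyError(
                f"element {element!r} not in reference {self.source!r}; "
                f"available: {sorted(self.values)}"
            )
        return self.values[element]


def describe(values, element: str = "") -> SummaryRow:
    """Summary statistics of a concentration vector (n >= 2, all finite)."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean > 0:
        cv, cv_ok = 100.0 * sd / mean, True
    else:
        cv, cv_ok = float("nan"), False
    if sd == 0:
        cv = 0.0 if cv_ok else cv
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=False, bias=False))
    return SummaryRow(
        element=element,
        n=int(x.size),
        mean=mean,
        median=float(np.median(x)),
        min=float(x.min()),
        max=float(x.max()),
        sd=sd,
        cv_percent=cv,
        skewness=skew,
        kurtosis=kurt,
        cv_defined=cv_ok,
    )


def _fold(mean: float, reference: ReferenceTable, element: str, ndigits: int) -> float:
    return round_half_up(mean / reference[element], ndigits)


def enrichment_ratios(summary: SummaryRow, reference: ReferenceTable) -> float:
    """Fold enrichment of the survey mean over a background value (2 dp)."""
    return _fold(summary.mean, reference, summary.element, 2)


def compare_external(summary: SummaryRow, literature: ReferenceTable) -> float:
    """Fold comparison of the survey mean against a literature mean (1 dp)."""
    return _fold(summary.mean, literature, summary.element, 1)


def load_references() -> dict:
    """Packaged reference tables (soil backgrounds + literature city means).

    Returns {source_name: ReferenceTable}. Values reproduce published
    background and literature concentration tables for the five elements
    Pb, Cu, Zn, Cr, Cd (mg/kg).
    """
    text = resources.files("soilkrige").joinpath("data/references.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for group in ("backgrounds", "literature"):
        for name, vals in raw[group].items():
            out[name] = ReferenceTable(
                source=name, values={k: float(v) for k, v in vals.items() if v is not None}
            )
    return out


def load_printed_tables() -> dict:
    """Packaged published-survey numbers used as computation inputs.

    Includes the printed per-element summary rows (mean/median/min/max/SD),
    fitted variogram parameters, and the MKV-by-points-perturbed rows of the
    reference Shanghai green-space survey.
    """
    text = resources.files("soilkrige").joinpath("data/references.yaml").read_text()
    raw = yaml.safe_load(text)
    return {k: raw[k] for k in ("printed_summary", "printed_variograms", "printed_mkv")}
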
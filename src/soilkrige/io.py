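"""File formats: sample tables (CSV), study regions (GeoJSON), rasters
(ESRI ASCII grid).

Sample tables are delimited text with a header of ``id,x,y`` plus one or
more element concentration columns (mg/kg; coordinates planar metres).
Values below an element's limit of detection (LOD) are flagged — never
dropped or substituted. Grids round-trip through the 6-line ESRI ASCII
header with NODATA -9999 for out-of-region cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .constants import EPS_DUP, NODATA
from .kriging import KrigingGrid


@dataclass
class SampleSet:
    """Point observations: ids, planar coordinates, element concentrations.

    ``table`` holds columns id, x, y plus one column per element.
    ``lod``/``loq`` (mg/kg) are optional detection/quantification limits per
    element; when only the LOD is given the LOQ defaults to 4*LOD.
    ``below_lod`` maps element -> boolean flag array.
    """

    table: pd.DataFrame
    lod: dict = field(default_factory=dict)
    loq: dict = field(default_factory=dict)

    def __post_init__(self):
        req = {"id", "x", "y"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"sample table must have columns {sorted(req)}")
        if self.table["id"].duplicated().any():
            dup = self.table.loc[self.table["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if not np.all(np.isfinite(self.table[["x", "y"]].to_numpy(float))):
            raise ValueError("non-finite coordinates")
        if not self.elements:
            raise ValueError("sample table has no element columns")
        coords = self.coords
        if len(coords) >= 2:
            d = pdist(coords)
            if float(d.min()) < EPS_DUP:
                dm = squareform(d)
                np.fill_diagonal(dm, np.inf)
                i, j = np.unravel_index(np.argmin(dm), dm.shape)
                raise ValueError(
                    f"duplicate coordinates within {EPS_DUP} m at rows {i} and {j}"
                )
        for el in self.elements:
            v = self.table[el].to_numpy(float)
            if not np.all(np.isfinite(v)):
                bad = int(np.flatnonzero(~np.isfinite(v))[0])
                raise ValueError(f"non-numeric/non-finite value for {el} at row {bad}")
            if np.any(v <= 0):
                bad = int(np.flatnonzero(v <= 0)[0])
                raise ValueError(f"non-positive concentration for {el} at row {bad}")
        for el, lim in list(self.lod.items()):
            self.loq.setdefault(el, 4.0 * lim)

    @property
    def elements(self) -> list:
        return [c for c in self.table.columns if c not in ("id", "x", "y")]

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)

    @property
    def n(self) -> int:
        return len(self.table)

    def values(self, element: str) -> np.ndarray:
        if element not in self.elements:
            raise KeyError(f"no element {element!r}; have {self.elements}")
        return self.table[element].to_numpy(float)

    @property
    def below_lod(self) -> dict:
        return {
            el: self.values(el) < lim for el, lim in self.lod.items() if el in self.elements
        }

    def subset(self, keep: np.ndarray) -> "SampleSet":
        return SampleSet(
            table=self.table.iloc[np.asarray(keep)].reset_index(drop=True),
            lod=dict(self.lod),
            loq=dict(self.loq),
        )

    @classmethod
    def from_arrays(cls, coords, values, element: str = "value", ids=None, **kw) -> "SampleSet":
        coords = np.asarray(coords, float)
        if ids is None:
            ids = [f"s{i:04d}" for i in range(len(coords))]
        tab = pd.DataFrame(
            {"id": ids, "x": coords[:, 0], "y": coords[:, 1], element: np.asarray(values, float)}
        )
        return cls(table=tab, **kw)


def read_samples(path, delimiter: str = ",", lod: dict | None = None) -> SampleSet:
    """Read a delimited sample table (header: id,x,y,<element>...)."""
    try:
        tab = pd.read_csv(path, delimiter=delimiter)
    except Exception as exc:
        raise ValueError(f"cannot parse sample table {path}: {exc}") from exc
    missing = {"id", "x", "y"} - set(tab.columns)
    if missing:
        raise ValueError(f"sample table {path} missing columns {sorted(missing)}")
    for col in tab.columns:
        if col == "id":
            continue
        coerced = pd.to_numeric(tab[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(f"non-numeric cell in column {col!r} at row {row}")
        tab[col] = coerced
    return SampleSet(table=tab, lod=dict(lod or {}))


def write_samples(samples: SampleSet, path) -> None:
    samples.table.to_csv(path, index=False)


def write_grid(grid: KrigingGrid, path, layer: str = "variances") -> None:
    """Write one grid layer as ESRI ASCII (NODATA -9999, 6 significant digits)."""
    arr = getattr(grid, layer)
    body = np.where(grid.mask, arr, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.xll:.6f}\n")
        fh.write(f"yllcorner {grid.yll:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {int(NODATA)}\n")
        for row in body:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array with NaN at NODATA, header)."""
    header = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    body = np.loadtxt(lines[6:]).reshape(n_rows, n_cols)
    body = np.where(body == header["nodata_value"], np.nan, body)
    return body, header
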
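"""Study-region polygons on an abstract planar metric plane.

Coordinates are planar metres throughout; no geographic CRS handling is
attempted. The region delimits where prediction-grid cells live and where
sampling designs may place points.
"""

from __future__ import annotations

import json

import numpy as np
import shapely
from shapely.geometry import Polygon, MultiPolygon, mapping, shape


class Region:
    """A planar study region (polygon, optionally with holes).

    Parameters
    ----------
    geometry
        A shapely ``Polygon`` or ``MultiPolygon`` in planar metres. Must be
        valid (closed, non-self-intersecting rings) with strictly positive
        area.
    """

    def __init__(self, geometry: Polygon | MultiPolygon):
        if not isinstance(geometry, (Polygon, MultiPolygon)):
            raise TypeError(
                f"Region requires a Polygon or MultiPolygon, got {type(geometry).__name__}"
            )
        if not geometry.is_valid:
            raise ValueError(f"invalid region geometry: {shapely.is_valid_reason(geometry)}")
        if geometry.area <= 0:
            raise ValueError("region has zero area")
        self.geometry = geometry

    @classmethod
    def rectangle(cls, minx: float, miny: float, maxx: float, maxy: float) -> "Region":
        return cls(shapely.box(minx, miny, maxx, maxy))

    @classmethod
    def from_geojson(cls, path) -> "Region":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("type") == "FeatureCollection":
            obj = obj["features"][0]["geometry"]
        elif obj.get("type") == "Feature":
            obj = obj["geometry"]
        return cls(shape(obj))

    def to_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(mapping(self.geometry), fh)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the region envelope."""
        return self.geometry.bounds

    @property
    def bbox_diagonal(self) -> float:
        minx, miny, maxx, maxy = self.bbox
        return float(np.hypot(maxx - minx, maxy - miny))

    @property
    def area(self) -> float:
        return self.geometry.area

    def contains(self, x, y) -> np.ndarray:
        """Vectorized strict-interior point-in-region test."""
        return shapely.contains_xy(self.geometry, np.asarray(x, float), np.asarray(y, float))

    def contains_points(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, float))
        return self.contains(coords[:, 0], coords[:, 1])

    def __repr__(self) -> str:  # pragma: no cover
        minx, miny, maxx, maxy = self.bbox
        return (
            f"Region(area={self.area:.6g} m², "
            f"bbox=({minx:.6g}, {miny:.6g}, {maxx:.6g}, {maxy:.6g}))"
        )
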
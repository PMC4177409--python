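"""Fishnet grid construction and station-to-cell assignment.

The assessment grid is a regular net of square cells built in ETRS89
geographic coordinates with a 1:1 angular cell-size ratio (the nominal
50 km mesh of the Mediterranean assessment corresponds to roughly 0.45°
meridionally; the side length is an angular parameter here). Cells are
half-open rectangles [lon0, lon0+d) x [lat0, lat0+d); points on the net's
outer top/right boundary belong to the last row/column so the net exactly
covers its bounding box.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from shapely.geometry import box, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity

__all__ = [
    "DEFAULT_CELL_SIZE_DEG",
    "Fishnet",
    "make_fishnet",
    "cell_of",
    "cell_bounds",
    "SubregionGrid",
    "clip_to_subregion",
    "grid_to_geojson",
    "load_polygon",
]

#: Default angular cell side, ~50 km meridionally in the Mediterranean.
DEFAULT_CELL_SIZE_DEG = 0.45

# tolerance for float noise when sizing the net from bbox / cell ratios
_EPS = 1e-9


@dataclass(frozen=True)
class Fishnet:
    """A regular angular grid anchored at its lower-left corner."""

    origin_lon: float
    origin_lat: float
    cell_size_deg: float
    n_rows: int
    n_cols: int
    crs_label: str = "ETRS89-geographic"

    def __post_init__(self) -> None:
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("fishnet needs at least one row and column")

    @property
    def max_lon(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size_deg

    @property
    def max_lat(self) -> float:
        return self.origin_lat + self.n_rows * self.cell_size_deg


def make_fishnet(
    bbox: tuple[float, float, float, float], cell_size_deg: float
) -> Fishnet:
    """Build the smallest fishnet covering ``bbox = (min_lon, min_lat,
    max_lon, max_lat)``; column/row counts are ceilinged so the net always
    covers the box."""
    min_lon, min_lat, max_lon, max_lat = bbox
    if not (min_lon < max_lon and min_lat < max_lat):
        raise ValueError(f"degenerate bounding box {bbox}")
    if cell_size_deg <= 0:
        raise ValueError("cell_size_deg must be positive")
    n_cols = max(1, math.ceil((max_lon - min_lon) / cell_size_deg - _EPS))
    n_rows = max(1, math.ceil((max_lat - min_lat) / cell_size_deg - _EPS))
    return Fishnet(
        origin_lon=min_lon,
        origin_lat=min_lat,
        cell_size_deg=cell_size_deg,
        n_rows=n_rows,
        n_cols=n_cols,
    )


def cell_of(
    net: Fishnet, lon: float, lat: float
) -> Optional[tuple[int, int]]:
    """Cell id ``(row, col)`` containing the point, or ``None`` outside.

    Half-open convention: a point on a shared edge belongs to the cell for
    which it is the lower/left bound; the net's outer top/right boundary is
    closed so boundary points still map to the last row/column.
    """
    d = net.cell_size_deg
    if not (net.origin_lon <= lon <= net.max_lon):
        return None
    if not (net.origin_lat <= lat <= net.max_lat):
        return None
    col = int((lon - net.origin_lon) // d)
    row = int((lat - net.origin_lat) // d)
    if col == net.n_cols:  # point exactly on the outer right edge
        col -= 1
    if row == net.n_rows:
        row -= 1
    return row, col


def cell_bounds(
    net: Fishnet, row: int, col: int
) -> tuple[float, float, float, float]:
    """``(lon0, lat0, lon1, lat1)`` of cell ``(row, col)``."""
    if not (0 <= row < net.n_rows and 0 <= col < net.n_cols):
        raise ValueError(f"cell ({row}, {col}) outside the net")
    d = net.cell_size_deg
    lon0 = net.origin_lon + col * d
    lat0 = net.origin_lat + row * d
    return lon0, lat0, lon0 + d, lat0 + d


@dataclass
class SubregionGrid:
    """A fishnet clipped to a subregion polygon.

    ``in_subregion`` holds the ids of cells whose rectangle intersects the
    polygon (boundary touch counts); ``total_cells`` is their count — the
    denominator of the spatial-coverage statistic.
    """

    fishnet: Fishnet
    polygon: BaseGeometry
    in_subregion: frozenset = field(default_factory=frozenset)

    @property
    def total_cells(self) -> int:
        return len(self.in_subregion)


def clip_to_subregion(net: Fishnet, polygon: BaseGeometry) -> SubregionGrid:
    """Mark the cells intersecting the subregion polygon."""
    if polygon.is_empty:
        raise ValueError("empty subregion polygon")
    if not polygon.is_valid:
        raise ValueError(
            f"invalid subregion geometry: {explain_validity(polygon)}"
        )
    cells = []
    for row in range(net.n_rows):
        for col in range(net.n_cols):
            rect = box(*cell_bounds(net, row, col))
            if rect.intersects(polygon):
                cells.append((row, col))
    return SubregionGrid(
        fishnet=net, polygon=polygon, in_subregion=frozenset(cells)
    )


def grid_to_geojson(grid: SubregionGrid) -> dict:
    """GeoJSON FeatureCollection of every net cell with properties
    ``row``, ``col``, ``in_subregion``."""
    net = grid.fishnet
    features = []
    for row in range(net.n_rows):
        for col in range(net.n_cols):
            lon0, lat0, lon1, lat1 = cell_bounds(net, row, col)
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [
                                [lon0, lat0],
                                [lon1, lat0],
                                [lon1, lat1],
                                [lon0, lat1],
                                [lon0, lat0],
                            ]
                        ],
                    },
                    "properties": {
                        "row": row,
                        "col": col,
                        "in_subregion": (row, col) in grid.in_subregion,
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}


def load_polygon(path: Union[str, Path]) -> BaseGeometry:
    """Load a (multi)polygon from a GeoJSON file (geographic lon-lat)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if data.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in data["features"]]
        geom = geoms[0] if len(geoms) == 1 else shape(
            {
                "type": "GeometryCollection",
                "geometries": [g.__geo_interface__ for g in geoms],
            }
        )
    elif data.get("type") == "Feature":
        geom = shape(data["geometry"])
    else:
        geom = shape(data)
    if geom.is_empty:
        raise ValueError(f"{path}: empty geometry")
    return geom
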
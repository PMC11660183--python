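"""Temporospatial churn: hexagonal binning of store openings and closings.

Stores are point-located in WGS84, projected to a local planar frame in US
feet, and assigned to a flat-top hexagonal grid whose adjacent centroids are
``spacing_ft`` apart (default 2640 ft = half a mile, roughly a ten-minute
walk between centroids). A custom hex geography is used instead of
administrative boundaries to limit modifiable-areal-unit effects. Per cell
and per class group, churn is summarized as the mean annual change in the
number of operating stores between two years:

    mean_annual_change = (count_y1 - count_y0) / (y1 - y0)

which — by telescoping — equals the mean of the consecutive annual
differences. A store counts as operating in calendar year ``y`` when its
evident operating interval (first inspection date through out-of-business
date, or last inspection date if still open) intersects that year.

Coordinate handling: full EPSG CRS machinery (pyproj) is deliberately not a
dependency; an equirectangular projection about the grid origin, exact enough
at city scale, provides the planar feet frame (``crs_id='local-feet'``).
Geographic CRS identifiers are rejected.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .classes import FoodClass, LabelSet
from .records import StoreRecord

__all__ = [
    "BBox",
    "LocalFeetProjection",
    "HexGrid",
    "OperatingInterval",
    "ChurnMap",
    "build_hex_grid",
    "operating_interval",
    "operating_years",
    "mean_annual_change",
]

logger = logging.getLogger(__name__)

#: Mean Earth radius in feet (6371008.8 m / 0.3048).
_EARTH_RADIUS_FT = 6371008.8 / 0.3048

_GEOGRAPHIC_CRS_IDS = {"epsg:4326", "epsg:4269", "wgs84", "crs84", "ogc:crs84"}


@dataclass(frozen=True)
class BBox:
    """Geographic bounding box in decimal degrees (WGS84)."""

    min_lon: float
    min_lat: float
    max_lon: float
    max_lat: float

    def __post_init__(self):
        if not (self.min_lon < self.max_lon and self.min_lat < self.max_lat):
            raise ValueError("bounding box is degenerate")

    @property
    def center(self) -> Tuple[float, float]:
        return (
            0.5 * (self.min_lon + self.max_lon),
            0.5 * (self.min_lat + self.max_lat),
        )

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.min_lon <= lon <= self.max_lon
            and self.min_lat <= lat <= self.max_lat
        )


@dataclass(frozen=True)
class LocalFeetProjection:
    """Equirectangular projection: WGS84 degrees -> feet about an origin."""

    lon0: float
    lat0: float

    def to_xy(self, lon: float, lat: float) -> Tuple[float, float]:
        k = _EARTH_RADIUS_FT * math.pi / 180.0
        x = (lon - self.lon0) * k * math.cos(math.radians(self.lat0))
        y = (lat - self.lat0) * k
        return x, y

    def to_lonlat(self, x: float, y: float) -> Tuple[float, float]:
        k = _EARTH_RADIUS_FT * math.pi / 180.0
        lon = self.lon0 + x / (k * math.cos(math.radians(self.lat0)))
        lat = self.lat0 + y / k
        return lon, lat


def _axial_round(qf: float, rf: float) -> Tuple[int, int]:
    # Cube-coordinate rounding; fixes the component with the largest error.
    sf = -qf - rf
    q, r, s = round(qf), round(rf), round(sf)
    dq, dr, ds = abs(q - qf), abs(r - rf), abs(s - sf)
    if dq > dr and dq > ds:
        q = -r - s
    elif dr > ds:
        r = -q - s
    return int(q), int(r)


@dataclass
class HexGrid:
    """Flat-top hexagonal grid over a projected bounding box.

    Centroids sit on the axial lattice ``x = 1.5*R*q``,
    ``y = sqrt(3)*R*(r + q/2)`` with circumradius ``R = spacing/sqrt(3)``, so
    every pair of adjacent centroids is exactly ``spacing`` apart and the
    hexagons are the Voronoi cells of the centroids (nearest-centroid
    assignment == polygon containment).
    """

    bbox: BBox
    centroid_spacing: float = 2640.0
    crs_id: str = "local-feet"
    projection: LocalFeetProjection = None  # type: ignore[assignment]
    cells: Dict[Tuple[int, int], Tuple[float, float]] = field(default_factory=dict)

    @property
    def circumradius(self) -> float:
        return self.centroid_spacing / math.sqrt(3.0)

    def centroid_xy(self, q: int, r: int) -> Tuple[float, float]:
        R = self.circumradius
        return 1.5 * R * q, math.sqrt(3.0) * R * (r + q / 2.0)

    def cell_of_xy(self, x: float, y: float) -> Tuple[int, int]:
        """Axial index of the cell containing a projected point."""
        R = self.circumradius
        qf = x / (1.5 * R)
        rf = y / (math.sqrt(3.0) * R) - qf / 2.0
        return _axial_round(qf, rf)

    def cell_of(self, lon: float, lat: float) -> Tuple[int, int]:
        """Axial index of the cell containing a WGS84 point."""
        return self.cell_of_xy(*self.projection.to_xy(lon, lat))

    def cell_polygon_lonlat(self, q: int, r: int) -> List[Tuple[float, float]]:
        """Closed ring of the hexagon's vertices in lon/lat (GeoJSON order)."""
        cx, cy = self.centroid_xy(q, r)
        R = self.circumradius
        ring = []
        for k in range(6):
            ang = math.radians(60.0 * k)
            ring.append(
                self.projection.to_lonlat(cx + R * math.cos(ang), cy + R * math.sin(ang))
            )
        ring.append(ring[0])
        return ring


def build_hex_grid(
    bbox: BBox | Tuple[float, float, float, float],
    spacing_ft: float = 2640.0,
    crs_id: str = "local-feet",
) -> HexGrid:
    """Build a flat-top hex grid covering ``bbox`` with the given centroid spacing.

    ``crs_id`` must name a projected frame; the built-in frame is
    ``'local-feet'``. Geographic identifiers (EPSG:4326 and friends) are
    rejected with instructions to use a projected CRS.
    """
    if not isinstance(bbox, BBox):
        bbox = BBox(*bbox)
    if spacing_ft <= 0:
        raise ValueError("spacing must be positive")
    key = crs_id.strip().lower()
    if key in _GEOGRAPHIC_CRS_IDS:
        raise ValueError(
            f"{crs_id!r} is a geographic (unprojected) CRS; hex binning needs a "
            "projected CRS with linear units — use 'local-feet'"
        )
    if key != "local-feet":
        raise ValueError(
            f"unsupported crs_id {crs_id!r}; this build supports the "
            "'local-feet' equirectangular frame"
        )
    lon0, lat0 = bbox.center
    proj = LocalFeetProjection(lon0=lon0, lat0=lat0)
    grid = HexGrid(
        bbox=bbox, centroid_spacing=float(spacing_ft), crs_id=crs_id, projection=proj
    )
    # Enumerate every cell whose hexagon can intersect the bbox.
    x0, y0 = proj.to_xy(bbox.min_lon, bbox.min_lat)
    x1, y1 = proj.to_xy(bbox.max_lon, bbox.max_lat)
    R = grid.circumradius
    q_min = math.floor((x0 - R) / (1.5 * R)) - 1
    q_max = math.ceil((x1 + R) / (1.5 * R)) + 1
    for q in range(q_min, q_max + 1):
        r_min = math.floor((y0 - R) / (math.sqrt(3.0) * R) - q / 2.0) - 1
        r_max = math.ceil((y1 + R) / (math.sqrt(3.0) * R) - q / 2.0) + 1
        for r in range(r_min, r_max + 1):
            cx, cy = grid.centroid_xy(q, r)
            if (
                x0 - grid.centroid_spacing <= cx <= x1 + grid.centroid_spacing
                and y0 - grid.centroid_spacing <= cy <= y1 + grid.centroid_spacing
            ):
                grid.cells[(q, r)] = (cx, cy)
    return grid


@dataclass(frozen=True)
class OperatingInterval:
    """Evident dates of operation: first inspection through closure/last sight."""

    start: dt.date
    end: Optional[dt.date]

    def __post_init__(self):
        if self.end is not None and self.start > self.end:
            raise ValueError("interval start exceeds end")

    def operates_in_year(self, year: int) -> bool:
        """True when the interval intersects [year-01-01, year-12-31]."""
        if self.start.year > year:
            return False
        return self.end is None or self.end.year >= year


def operating_interval(record: StoreRecord) -> OperatingInterval:
    """Derive the evident operating interval from inspection/closure dates.

    Start is the earliest inspection date; end is the recorded
    out-of-business date when present, otherwise the latest inspection date.
    """
    if not record.inspection_dates:
        raise ValueError(
            f"record {record.record_id!r} has no inspection dates"
        )
    start = record.inspection_dates[0]
    end = (
        record.out_of_business_date
        if record.out_of_business_date is not None
        else record.inspection_dates[-1]
    )
    return OperatingInterval(start=start, end=end)


def operating_years(record: StoreRecord) -> range:
    """Calendar years during which the record evidently operates."""
    iv = operating_interval(record)
    return range(iv.start.year, iv.end.year + 1)


@dataclass
class ChurnMap:
    """Per-hexbin mean annual change in operating counts for a class group."""

    grid: HexGrid
    class_group: frozenset
    y0: int
    y1: int
    count_y0: Dict[Tuple[int, int], int]
    count_y1: Dict[Tuple[int, int], int]

    def mean_annual_change_of(self, cell: Tuple[int, int]) -> float:
        return (self.count_y1.get(cell, 0) - self.count_y0.get(cell, 0)) / (
            self.y1 - self.y0
        )

    @property
    def values(self) -> Dict[Tuple[int, int], float]:
        return {cell: self.mean_annual_change_of(cell) for cell in self.grid.cells}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (q, r) in sorted(self.grid.cells):
            rows.append(
                {
                    "q": q,
                    "r": r,
                    f"count_{self.y0}": self.count_y0.get((q, r), 0),
                    f"count_{self.y1}": self.count_y1.get((q, r), 0),
                    "mean_annual_change": self.mean_annual_change_of((q, r)),
                }
            )
        return pd.DataFrame(rows)

    def to_geojson(self) -> dict:
        """FeatureCollection of hexagon polygons with churn properties."""
        features = []
        for (q, r) in sorted(self.grid.cells):
            ring = [
                [round(lon, 8), round(lat, 8)]
                for lon, lat in self.grid.cell_polygon_lonlat(q, r)
            ]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "q": q,
                        "r": r,
                        "count_y0": self.count_y0.get((q, r), 0),
                        "count_y1": self.count_y1.get((q, r), 0),
                        "mean_annual_change": self.mean_annual_change_of((q, r)),
                    },
                }
            )
        return {
            "type": "FeatureCollection",
            "features": features,
            "properties": {
                "crs_id": self.grid.crs_id,
                "centroid_spacing_ft": self.grid.centroid_spacing,
                "class_group": sorted(c.value for c in self.class_group),
                "y0": self.y0,
                "y1": self.y1,
            },
        }

    def save_geojson(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)


def mean_annual_change(
    records: Sequence[Tuple[StoreRecord, LabelSet]],
    grid: HexGrid,
    class_group: Set[FoodClass],
    y0: int,
    y1: int,
) -> ChurnMap:
    """Per-cell mean annual change in operating counts for a class group.

    A record contributes to a cell-year count iff its labels intersect
    ``class_group`` and its operating interval intersects that year; class
    groups are matched by label-set intersection, so a store carrying both
    Grocery and Convenience counts in maps of either group. Records without
    inspection dates are excluded with a warning. All grid cells appear in
    the result, zero-count cells included.
    """
    if not class_group:
        raise ValueError("class_group must be non-empty")
    if y1 <= y0:
        raise ValueError(f"need y1 > y0, got {y0}..{y1}")
    group = frozenset(class_group)
    count_y0: Dict[Tuple[int, int], int] = {cell: 0 for cell in grid.cells}
    count_y1: Dict[Tuple[int, int], int] = {cell: 0 for cell in grid.cells}
    n_skipped = 0
    for rec, labels in records:
        if not (frozenset(labels) & group):
            continue
        if not rec.inspection_dates:
            n_skipped += 1
            continue
        iv = operating_interval(rec)
        cell = grid.cell_of(rec.longitude, rec.latitude)
        if iv.operates_in_year(y0):
            count_y0[cell] = count_y0.get(cell, 0) + 1
        if iv.operates_in_year(y1):
            count_y1[cell] = count_y1.get(cell, 0) + 1
    if n_skipped:
        logger.warning(
            "%d records had no inspection dates and were excluded", n_skipped
        )
    return ChurnMap(
        grid=grid,
        class_group=group,
        y0=y0,
        y1=y1,
        count_y0=count_y0,
        count_y1=count_y1,
    )
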
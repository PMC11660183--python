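"""Hexagonal binning geometry and mean-annual-change churn surfaces."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from foodenv.churn import (
    BBox,
    build_hex_grid,
    mean_annual_change,
    operating_interval,
    operating_years,
)
from foodenv.classes import FoodClass
from foodenv.records import StoreRecord

NYC = BBox(-74.05, 40.60, -73.85, 40.75)


@pytest.fixture(scope="module")
def grid():
    return build_hex_grid(NYC, 2640.0)


# --- grid geometry ----------------------------------------------------------


def test_adjacent_centroids_are_half_a_mile_apart(grid):
    """Every neighboring pair of centroids is exactly 2640 ft apart."""
    cells = grid.cells
    neighbors = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]
    checked = 0
    for (q, r), (x, y) in list(cells.items())[:200]:
        for dq, dr in neighbors:
            if (q + dq, r + dr) in cells:
                nx, ny = cells[(q + dq, r + dr)]
                assert math.hypot(nx - x, ny - y) == pytest.approx(2640.0, rel=1e-6)
                checked += 1
    assert checked > 100


def test_tiny_bbox_still_covered():
    tiny = BBox(-73.99, 40.70, -73.989, 40.701)  # far smaller than one cell
    grid = build_hex_grid(tiny, 2640.0)
    assert len(grid.cells) >= 1
    cell = grid.cell_of(*tiny.center)
    assert cell in grid.cells


def test_geographic_crs_rejected():
    with pytest.raises(ValueError, match="projected"):
        build_hex_grid(NYC, 2640.0, crs_id="EPSG:4326")


def test_point_maps_to_nearest_centroid(grid):
    """Cell assignment equals the brute-force nearest-centroid oracle."""
    rng = np.random.default_rng(11)
    centroids = grid.cells
    keys = list(centroids)
    xy = np.array([centroids[k] for k in keys])
    for _ in range(200):
        lon = rng.uniform(NYC.min_lon, NYC.max_lon)
        lat = rng.uniform(NYC.min_lat, NYC.max_lat)
        x, y = grid.projection.to_xy(lon, lat)
        nearest = keys[int(np.argmin((xy[:, 0] - x) ** 2 + (xy[:, 1] - y) ** 2))]
        assert grid.cell_of(lon, lat) == nearest


def test_assigned_hexagon_contains_the_point(grid):
    """Independent geometric oracle: the cell polygon contains the point."""
    rng = np.random.default_rng(13)
    for _ in range(50):
        lon = rng.uniform(NYC.min_lon, NYC.max_lon)
        lat = rng.uniform(NYC.min_lat, NYC.max_lat)
        q, r = grid.cell_of(lon, lat)
        poly = Polygon(grid.cell_polygon_lonlat(q, r))
        assert poly.buffer(1e-9).contains(Point(lon, lat))


# --- operating intervals ----------------------------------------------------


def make_store(inspections, oob=None, lon=-73.95, lat=40.70, rid="s1"):
    return StoreRecord(
        record_id=rid, name="Test Grocery", longitude=lon, latitude=lat,
        inspection_dates=tuple(sorted(inspections)), out_of_business_date=oob,
    )


def test_interval_from_inspections_only():
    rec = make_store([dt.date(2015, 3, 1), dt.date(2018, 6, 1)])
    iv = operating_interval(rec)
    assert iv.start == dt.date(2015, 3, 1) and iv.end == dt.date(2018, 6, 1)
    assert list(operating_years(rec)) == [2015, 2016, 2017, 2018]


def test_out_of_business_date_closes_interval():
    rec = make_store([dt.date(2019, 5, 1)], oob=dt.date(2020, 2, 1))
    assert [iv for iv in operating_years(rec)] == [2019, 2020]
    assert not operating_interval(rec).operates_in_year(2021)


def test_no_inspections_is_an_error():
    with pytest.raises(ValueError, match="no inspection dates"):
        operating_interval(make_store([]))


def test_year_membership_matches_interval_intersection():
    rng = np.random.default_rng(5)
    for _ in range(50):
        days = sorted(rng.integers(0, 3650, size=rng.integers(1, 5)))
        dates = [dt.date(2013, 1, 1) + dt.timedelta(days=int(d)) for d in days]
        oob = dates[-1] + dt.timedelta(days=int(rng.integers(0, 400))) if rng.random() < 0.5 else None
        rec = make_store(dates, oob=oob)
        iv = operating_interval(rec)
        for year in range(2012, 2026):
            expected = iv.start <= dt.date(year, 12, 31) and (
                iv.end is None or iv.end >= dt.date(year, 1, 1)
            )
            assert iv.operates_in_year(year) == expected


# --- mean annual change -----------------------------------------------------

G = frozenset({FoodClass.GROCERY})
C = frozenset({FoodClass.CONVENIENCE})


def test_static_directory_has_zero_churn(grid):
    records = [
        (make_store([dt.date(2019, 2, 1), dt.date(2021, 11, 1)], rid=f"s{i}"), G)
        for i in range(20)
    ]
    cmap = mean_annual_change(records, grid, {FoodClass.GROCERY}, 2019, 2021)
    assert all(v == 0.0 for v in cmap.values.values())


def test_endpoint_difference_over_span(grid):
    """4 stores in 2019 down to 2 by 2021 in one cell -> -1.0 per year."""
    lon, lat = -73.95, 40.70
    cell = grid.cell_of(lon, lat)
    records = []
    for i in range(2):  # survive through 2021
        records.append((make_store([dt.date(2019, 3, 1), dt.date(2021, 6, 1)],
                                   lon=lon, lat=lat, rid=f"a{i}"), G))
    for i in range(2):  # close during 2019
        records.append((make_store([dt.date(2019, 3, 1)], oob=dt.date(2019, 12, 1),
                                   lon=lon, lat=lat, rid=f"b{i}"), G))
    cmap = mean_annual_change(records, grid, {FoodClass.GROCERY}, 2019, 2021)
    assert cmap.count_y0[cell] == 4 and cmap.count_y1[cell] == 2
    assert cmap.mean_annual_change_of(cell) == pytest.approx(-1.0)


def test_class_group_uses_labelset_intersection(grid):
    """A Grocery+Convenience store counts in maps of either group."""
    rec = make_store([dt.date(2019, 1, 5), dt.date(2021, 1, 5)])
    pair = [(rec, frozenset({FoodClass.GROCERY, FoodClass.CONVENIENCE}))]
    for group in ({FoodClass.GROCERY}, {FoodClass.CONVENIENCE}):
        cmap = mean_annual_change(pair, grid, group, 2019, 2021)
        assert sum(cmap.count_y0.values()) == 1


def test_churn_additive_over_label_disjoint_groups(grid):
    rng = np.random.default_rng(23)
    records = []
    for i in range(60):
        lon = rng.uniform(NYC.min_lon, NYC.max_lon)
        lat = rng.uniform(NYC.min_lat, NYC.max_lat)
        start = dt.date(2019, 1, 1) + dt.timedelta(days=int(rng.integers(0, 700)))
        oob = start + dt.timedelta(days=int(rng.integers(30, 900))) if rng.random() < 0.5 else None
        labels = G if i % 2 else C
        records.append((make_store([start], oob=oob, lon=lon, lat=lat, rid=f"s{i}"), labels))
    m_a = mean_annual_change(records, grid, {FoodClass.GROCERY}, 2019, 2021)
    m_b = mean_annual_change(records, grid, {FoodClass.CONVENIENCE}, 2019, 2021)
    m_ab = mean_annual_change(
        records, grid, {FoodClass.GROCERY, FoodClass.CONVENIENCE}, 2019, 2021
    )
    for cell in grid.cells:
        assert m_ab.mean_annual_change_of(cell) == pytest.approx(
            m_a.mean_annual_change_of(cell) + m_b.mean_annual_change_of(cell)
        )
    # and the cellwise sum telescopes to the directory-wide net change
    net = sum(m_ab.count_y1.values()) - sum(m_ab.count_y0.values())
    ops = [
        (operating_interval(r).operates_in_year(2021))
        - (operating_interval(r).operates_in_year(2019))
        for r, _ in records
    ]
    assert net == sum(ops)


def test_translation_invariance():
    """Shifting points and grid bbox together leaves counts unchanged."""
    rng = np.random.default_rng(31)
    base = build_hex_grid(NYC, 2640.0)
    # shift along the parallel so the local-feet scale factor is unchanged
    d_lon, d_lat = 0.8, 0.0
    shifted_bbox = BBox(
        NYC.min_lon + d_lon, NYC.min_lat + d_lat,
        NYC.max_lon + d_lon, NYC.max_lat + d_lat,
    )
    # keep the projection origin-relative geometry identical
    shifted = build_hex_grid(shifted_bbox, 2640.0)
    recs, recs_shifted = [], []
    for i in range(40):
        lon = rng.uniform(NYC.min_lon + 0.02, NYC.max_lon - 0.02)
        lat = rng.uniform(NYC.min_lat + 0.02, NYC.max_lat - 0.02)
        dates = [dt.date(2019, 6, 1), dt.date(2021, 6, 1)]
        recs.append((make_store(dates, lon=lon, lat=lat, rid=f"s{i}"), G))
        recs_shifted.append(
            (make_store(dates, lon=lon + d_lon, lat=lat + d_lat, rid=f"s{i}"), G)
        )
    m1 = mean_annual_change(recs, base, {FoodClass.GROCERY}, 2019, 2021)
    m2 = mean_annual_change(recs_shifted, shifted, {FoodClass.GROCERY}, 2019, 2021)
    assert m1.count_y0 == m2.count_y0
    assert m1.count_y1 == m2.count_y1


def test_empty_class_group_rejected(grid):
    with pytest.raises(ValueError, match="class_group"):
        mean_annual_change([], grid, set(), 2019, 2021)


def test_geojson_export_roundtrip(tmp_path, grid):
    import json

    rec = make_store([dt.date(2019, 1, 1), dt.date(2021, 1, 1)])
    cmap = mean_annual_change([(rec, G)], grid, {FoodClass.GROCERY}, 2019, 2021)
    path = tmp_path / "churn.geojson"
    cmap.save_geojson(path)
    doc = json.loads(path.read_text())
    assert doc["type"] == "FeatureCollection"
    assert len(doc["features"]) == len(grid.cells)
    feature = doc["features"][0]
    assert {"count_y0", "count_y1", "mean_annual_change", "q", "r"} <= set(
        feature["properties"]
    )
    ring = feature["geometry"]["coordinates"][0]
    assert len(ring) == 7 and ring[0] == ring[-1]
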
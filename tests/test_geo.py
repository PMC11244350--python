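import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from niche_shift.geo import (AUTHALIC_RADIUS_KM, AscFormatError, GeoPoint,
                             LatLonGrid, RasterLayer, RasterStack,
                             cell_area_map_km2, cell_band_area_km2, compass8,
                             dms_to_decimal, extract_values, geodesic_km,
                             great_circle_km, initial_bearing_deg, read_asc,
                             write_asc)

from conftest import make_layer


# ---------------------------------------------------------------------------
# ASC I/O
# ---------------------------------------------------------------------------

def test_asc_header_arithmetic(tmp_path):
    p = tmp_path / "g.asc"
    p.write_text("ncols 2\nnrows 2\nxllcorner 100\nyllcorner 20\ncellsize 1\n"
                 "NODATA_value -9999\n1 2\n3 4\n")
    layer = read_asc(p)
    center = layer.grid.cell_center(0, 0)
    assert center.lon_deg == pytest.approx(100.5)
    assert center.lat_deg == pytest.approx(21.5)
    # row 0 is the northern row
    assert layer.values[0, 0] == 1.0
    assert layer.values[1, 1] == 4.0


def test_asc_xllcenter_dialect(tmp_path):
    p = tmp_path / "g.asc"
    p.write_text("ncols 1\nnrows 1\nxllcenter 100.5\nyllcenter 20.5\ncellsize 1\n"
                 "7\n")
    layer = read_asc(p)
    assert layer.grid.west_deg == pytest.approx(100.0)
    assert layer.grid.south_deg == pytest.approx(20.0)


@pytest.mark.parametrize("body, msg", [
    ("ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n1 2 3\n1 2\n", "expected"),
    ("ncols 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n1 2\n", "nrows"),
    ("ncols 2\nnrows 1\nxllcorner 0\nxllcenter 1\nyllcorner 0\ncellsize 1\n1 2\n",
     "both"),
    ("ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 1\n1 x\n", "non-numeric"),
])
def test_asc_malformed(tmp_path, body, msg):
    p = tmp_path / "bad.asc"
    p.write_text(body)
    with pytest.raises(AscFormatError, match=msg):
        read_asc(p)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_asc_round_trip_random_layers(tmp_path_factory, seed):
    """write → read reproduces values, grid and nodata mask exactly."""
    rng = np.random.default_rng(seed)
    n_rows, n_cols = int(rng.integers(1, 8)), int(rng.integers(1, 8))
    vals = rng.normal(size=(n_rows, n_cols)) * 1000
    vals[rng.random((n_rows, n_cols)) < 0.2] = np.nan
    layer = make_layer(vals, west=float(rng.uniform(-170, 150)),
                       south=float(rng.uniform(-80, 60)),
                       cell=float(rng.uniform(0.01, 1.0)))
    path = tmp_path_factory.mktemp("asc") / "rt.asc"
    write_asc(layer, path)
    back = read_asc(path)
    assert back.grid == layer.grid
    np.testing.assert_array_equal(np.isnan(back.values), np.isnan(layer.values))
    np.testing.assert_array_equal(back.values[~np.isnan(layer.values)],
                                  layer.values[~np.isnan(layer.values)])


# ---------------------------------------------------------------------------
# Stacks and extraction
# ---------------------------------------------------------------------------

def test_stack_requires_shared_grid():
    a = make_layer(np.zeros((2, 2)), name="a")
    b = make_layer(np.zeros((3, 3)), name="b")
    with pytest.raises(Exception, match="different grid"):
        RasterStack([a, b])


def test_extract_values_index_arithmetic(toy_stack):
    # cells span lon 100-103, lat 20-23; value = row*10 + col with row 0 north
    pts = [GeoPoint(100.5, 22.5),   # row 0, col 0
           GeoPoint(102.5, 20.5),   # row 2, col 2
           GeoPoint(101.5, 21.5)]   # row 1, col 1
    out = extract_values(toy_stack, pts)
    assert out["code"].tolist() == [0.0, 22.0, 11.0]
    assert out["valid"].all()


def test_extract_values_edge_and_bounds(toy_stack):
    eps = 1e-9
    out = extract_values(toy_stack, [
        GeoPoint(100.0 - eps, 21.0),    # just west of the extent
        GeoPoint(101.0, 21.5),          # internal vertical edge -> west cell (col 0)
        GeoPoint(100.5, 22.0),          # internal horizontal edge -> north cell (row 0)
        GeoPoint(100.0, 20.0),          # extent corner stays in bounds
    ])
    assert not out.loc[0, "in_bounds"]
    assert out.loc[1, "code"] == 10.0   # row 1, col 0
    assert out.loc[2, "code"] == 0.0    # row 0, col 0
    assert out.loc[3, "in_bounds"]


def test_extract_flags_nodata_cells(toy_stack):
    layer = toy_stack.layers[0]
    vals = layer.values.copy()
    vals[1, 1] = np.nan
    stack = RasterStack([make_layer(vals, name="code")])
    out = extract_values(stack, [GeoPoint(101.5, 21.5)])
    assert out.loc[0, "in_bounds"] and not out.loc[0, "valid"]


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

def test_band_area_closed_form():
    grid = LatLonGrid(n_rows=1, n_cols=1, west_deg=0, south_deg=0, cell_deg=1.0)
    expected = AUTHALIC_RADIUS_KM ** 2 * math.radians(1.0) * math.sin(math.radians(1.0))
    assert cell_band_area_km2(grid, 0) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(1.2364e4, rel=1e-3)


@pytest.mark.parametrize("cell", [1.0, 2.0, 7.5])
def test_global_area_sums_to_sphere(cell):
    grid = LatLonGrid(n_rows=int(180 / cell), n_cols=int(360 / cell),
                      west_deg=-180, south_deg=-90, cell_deg=cell)
    total = cell_area_map_km2(grid).sum()
    assert total == pytest.approx(4 * math.pi * AUTHALIC_RADIUS_KM ** 2, rel=1e-6)


def test_band_area_equator_symmetry():
    grid = LatLonGrid(n_rows=4, n_cols=4, west_deg=0, south_deg=-2, cell_deg=1.0)
    # rows 1 and 2 straddle the equator symmetrically
    assert cell_band_area_km2(grid, 1) == pytest.approx(cell_band_area_km2(grid, 2))
    assert cell_band_area_km2(grid, 0) < cell_band_area_km2(grid, 1)


# ---------------------------------------------------------------------------
# Geodesics and bearings
# ---------------------------------------------------------------------------

def test_geodesic_identity_and_equator_degree():
    assert geodesic_km(GeoPoint(5, 5), GeoPoint(5, 5)) == 0.0
    # 1 degree of longitude along the equator on WGS84 (geosphere::distGeo oracle)
    assert geodesic_km(GeoPoint(0, 0), GeoPoint(1, 0)) == pytest.approx(111.3195,
                                                                        abs=1e-3)


def test_geodesic_matches_published_centroid_shift():
    a = GeoPoint(dms_to_decimal("109°23′53″E"), dms_to_decimal("27°30′08″N"))
    b = GeoPoint(dms_to_decimal("108°37′15″E"), dms_to_decimal("27°44′01″N"))
    # geosphere::distGeo gives 80.88832 km for this pair
    assert geodesic_km(a, b) == pytest.approx(80.888, abs=2e-3)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_geodesic_symmetry_and_sphere_agreement(seed):
    rng = np.random.default_rng(seed)
    a = GeoPoint(float(rng.uniform(-160, 160)), float(rng.uniform(25, 55)))
    b = GeoPoint(float(np.clip(a.lon_deg + rng.uniform(-10, 10), -180, 180)),
                 float(np.clip(a.lat_deg + rng.uniform(-10, 10), 25, 55)))
    d_ab, d_ba = geodesic_km(a, b), geodesic_km(b, a)
    assert d_ab == pytest.approx(d_ba, abs=1e-9)
    # spherical fallback within 0.5% on mid-latitude pairs
    if d_ab > 1.0:
        assert great_circle_km(a, b) == pytest.approx(d_ab, rel=5e-3)


def test_geodesic_triangle_inequality():
    pts = [GeoPoint(0, 0), GeoPoint(30, 20), GeoPoint(-10, 45), GeoPoint(100, -30)]
    for a in pts:
        for b in pts:
            for c in pts:
                assert geodesic_km(a, c) <= geodesic_km(a, b) + geodesic_km(b, c) + 1e-6


def test_compass8_sectors():
    origin = GeoPoint(0.0, 0.0)
    assert compass8(origin, GeoPoint(0.0, 1.0)) == "N"
    assert compass8(origin, GeoPoint(0.0, -1.0)) == "S"
    assert compass8(origin, GeoPoint(1.0, 0.0)) == "E"
    # 44.9 and 45.1 degrees both fall in the NE sector (centered at 45)
    for bearing in (44.9, 45.1):
        d = 0.01
        target = GeoPoint(d * math.sin(math.radians(bearing)),
                          d * math.cos(math.radians(bearing)))
        assert compass8(origin, target) == "NE"
    with pytest.raises(ValueError, match="coincident"):
        compass8(origin, origin)


def test_initial_bearing_due_east_at_equator():
    assert initial_bearing_deg(GeoPoint(10, 0), GeoPoint(11, 0)) == pytest.approx(90.0)


# ---------------------------------------------------------------------------
# DMS parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text, expected", [
    ("109°23′53″E", 109 + 23 / 60 + 53 / 3600),
    ("27°30′08″N", 27 + 30 / 60 + 8 / 3600),
    ("0°0′0″W", 0.0),
    ("45°30′W", -45.5),
    ("12°S", -12.0),
])
def test_dms_to_decimal(text, expected):
    assert dms_to_decimal(text) == pytest.approx(expected, abs=1e-9)


def test_dms_values(toy_stack=None):
    assert dms_to_decimal("109°23′53″E") == pytest.approx(109.398056, abs=1e-6)
    assert dms_to_decimal("27°30′08″N") == pytest.approx(27.502222, abs=1e-6)


@pytest.mark.parametrize("bad", ["109°61′0″E", "10°0′75″N", "garbage", "12°34′56″"])
def test_dms_rejects_invalid(bad):
    with pytest.raises(ValueError):
        dms_to_decimal(bad)
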
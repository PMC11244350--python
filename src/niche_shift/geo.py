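"""Grid/coordinate data model, Esri ASCII raster I/O, and geometry on the sphere/ellipsoid.

Conventions used throughout the package:

* Geographic coordinates are WGS84 decimal degrees, longitude east, latitude north.
* Rasters live on a shared latitude/longitude grid with square cells; row 0 is the
  northern-most row (the Esri ASCII convention).  ``xllcorner/yllcorner`` are the
  lower-left *corner*; the ``xllcenter`` dialect is accepted on read and converted.
* Nodata cells are represented internally as ``NaN``; the nodata sentinel only
  appears in files.
* Cell areas use the authalic sphere (R = 6371.0088 km); point-to-point distances
  use the WGS84 ellipsoid (Vincenty inverse) because printed migration distances
  are sharp enough to notice the difference.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AUTHALIC_RADIUS_KM",
    "AscFormatError",
    "GridMismatchError",
    "GeoPoint",
    "LatLonGrid",
    "RasterLayer",
    "RasterStack",
    "read_asc",
    "write_asc",
    "extract_values",
    "cell_band_area_km2",
    "cell_area_map_km2",
    "geodesic_km",
    "great_circle_km",
    "initial_bearing_deg",
    "compass8",
    "dms_to_decimal",
]

#: Radius of the sphere with the same surface area as the WGS84 ellipsoid, km.
AUTHALIC_RADIUS_KM = 6371.0088

# WGS84 ellipsoid, metres.
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)


class AscFormatError(ValueError):
    """Raised for malformed Esri ASCII grid files."""


class GridMismatchError(ValueError):
    """Raised when an operation requires layers/maps on an identical grid."""


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 point (decimal degrees east / north)."""

    lon_deg: float
    lat_deg: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon_deg <= 180.0):
            raise ValueError(f"longitude {self.lon_deg} outside [-180, 180]")
        if not (-90.0 <= self.lat_deg <= 90.0):
            raise ValueError(f"latitude {self.lat_deg} outside [-90, 90]")


@dataclass(frozen=True)
class LatLonGrid:
    """A regular lat/lon grid with square cells, row 0 at the north."""

    n_rows: int
    n_cols: int
    west_deg: float
    south_deg: float
    cell_deg: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_deg <= 0:
            raise ValueError("cell_deg must be positive")
        if self.west_deg < -180.0 or self.east_deg > 180.0 + 1e-9:
            raise ValueError("grid longitude extent outside [-180, 180]")
        if self.south_deg < -90.0 or self.north_deg > 90.0 + 1e-9:
            raise ValueError("grid latitude extent outside [-90, 90]")

    @property
    def east_deg(self) -> float:
        return self.west_deg + self.n_cols * self.cell_deg

    @property
    def north_deg(self) -> float:
        return self.south_deg + self.n_rows * self.cell_deg

    def cell_center(self, row: int, col: int) -> GeoPoint:
        lon = self.west_deg + (col + 0.5) * self.cell_deg
        lat = self.south_deg + (self.n_rows - row - 0.5) * self.cell_deg
        return GeoPoint(lon, lat)

    def lon_centers(self) -> np.ndarray:
        return self.west_deg + (np.arange(self.n_cols) + 0.5) * self.cell_deg

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 (north) first."""
        rows = np.arange(self.n_rows)
        return self.south_deg + (self.n_rows - rows - 0.5) * self.cell_deg

    def locate(self, lon_deg: float, lat_deg: float) -> tuple[int, int] | None:
        """Row/col of the cell containing a point, or ``None`` if outside the extent.

        A point on an internal cell edge belongs to the cell to the north/west
        of the edge (a deterministic tie-break); points on the outer boundary
        of the extent are inside.
        """
        fx = (lon_deg - self.west_deg) / self.cell_deg
        gy = (self.north_deg - lat_deg) / self.cell_deg
        if fx < 0 or fx > self.n_cols or gy < 0 or gy > self.n_rows:
            return None
        col = min(max(math.ceil(fx) - 1, 0), self.n_cols - 1)
        row = min(max(math.ceil(gy) - 1, 0), self.n_rows - 1)
        return row, col


@dataclass
class RasterLayer:
    """One named raster layer; ``values`` is (n_rows, n_cols) float with NaN nodata."""

    grid: LatLonGrid
    name: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"layer '{self.name}': values shape {self.values.shape} does not "
                f"match grid ({self.grid.n_rows}, {self.grid.n_cols})"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)


class RasterStack:
    """An ordered collection of :class:`RasterLayer` on one shared grid."""

    def __init__(self, layers: list[RasterLayer]):
        if not layers:
            raise ValueError("a RasterStack needs at least one layer")
        grid = layers[0].grid
        names = [lyr.name for lyr in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for lyr in layers[1:]:
            if lyr.grid != grid:
                raise GridMismatchError(
                    f"layer '{lyr.name}' is on a different grid than '{layers[0].name}'"
                )
        self.layers = list(layers)
        self.grid = grid
        self._by_name = {lyr.name: lyr for lyr in layers}

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def __getitem__(self, name: str) -> RasterLayer:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.layers)

    def valid_mask(self) -> np.ndarray:
        """Cells that are non-nodata in every layer."""
        mask = ~self.layers[0].nodata_mask
        for lyr in self.layers[1:]:
            mask &= ~lyr.nodata_mask
        return mask

    def to_array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) value cube."""
        return np.stack([lyr.values for lyr in self.layers])

    def subset(self, names: list[str]) -> "RasterStack":
        return RasterStack([self._by_name[n] for n in names])


# ---------------------------------------------------------------------------
# Esri ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value"}


def read_asc(path, name: str | None = None) -> RasterLayer:
    """Read an Esri ASCII grid.

    Headers ``ncols, nrows, xllcorner|xllcenter, yllcorner|yllcenter, cellsize``
    are required (any order, case-insensitive); ``NODATA_value`` defaults to
    -9999.  Center-registered headers are converted to corner registration.
    """
    headers: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split()
            key = parts[0].lower()
            if not data_lines and key in _HEADER_KEYS:
                if len(parts) != 2:
                    raise AscFormatError(f"malformed header line: {stripped!r}")
                try:
                    headers[key] = float(parts[1])
                except ValueError as exc:
                    raise AscFormatError(f"non-numeric header value: {stripped!r}") from exc
            else:
                data_lines.append(stripped)

    for req in ("ncols", "nrows", "cellsize"):
        if req not in headers:
            raise AscFormatError(f"missing required header '{req}'")
    if "xllcorner" in headers and "xllcenter" in headers:
        raise AscFormatError("both xllcorner and xllcenter present")
    if "yllcorner" in headers and "yllcenter" in headers:
        raise AscFormatError("both yllcorner and yllcenter present")

    cell = headers["cellsize"]
    if cell <= 0:
        raise AscFormatError(f"cellsize must be positive, got {cell}")
    n_cols = int(headers["ncols"])
    n_rows = int(headers["nrows"])
    if n_cols != headers["ncols"] or n_rows != headers["nrows"]:
        raise AscFormatError("ncols/nrows must be integers")

    if "xllcorner" in headers:
        west = headers["xllcorner"]
    elif "xllcenter" in headers:
        west = headers["xllcenter"] - cell / 2.0
    else:
        raise AscFormatError("missing xllcorner/xllcenter header")
    if "yllcorner" in headers:
        south = headers["yllcorner"]
    elif "yllcenter" in headers:
        south = headers["yllcenter"] - cell / 2.0
    else:
        raise AscFormatError("missing yllcorner/yllcenter header")

    nodata = headers.get("nodata_value", -9999.0)

    tokens: list[str] = []
    for ln in data_lines:
        tokens.extend(ln.split())
    if len(tokens) != n_rows * n_cols:
        raise AscFormatError(
            f"expected {n_rows * n_cols} values ({n_rows} rows x {n_cols} cols), "
            f"found {len(tokens)}"
        )
    try:
        values = np.array(tokens, dtype=float).reshape(n_rows, n_cols)
    except ValueError as exc:
        raise AscFormatError("non-numeric value in grid body") from exc
    values[values == nodata] = np.nan

    grid = LatLonGrid(n_rows=n_rows, n_cols=n_cols, west_deg=west,
                      south_deg=south, cell_deg=cell, nodata_value=nodata)
    if name is None:
        name = re.sub(r"\.asc$", "", str(path).rsplit("/", 1)[-1], flags=re.I)
    return RasterLayer(grid=grid, name=name, values=values)


def write_asc(layer: RasterLayer, path) -> None:
    """Write a layer as an Esri ASCII grid (corner-registered, %.17g values)."""
    g = layer.grid
    out = np.where(np.isnan(layer.values), g.nodata_value, layer.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.west_deg!r}\n")
        fh.write(f"yllcorner {g.south_deg!r}\n")
        fh.write(f"cellsize {g.cell_deg!r}\n")
        fh.write(f"NODATA_value {g.nodata_value:g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

def extract_values(stack: RasterStack, points: list[GeoPoint]) -> pd.DataFrame:
    """Nearest-cell (containment) layer values at each point.

    Returns a DataFrame with one column per layer plus ``in_bounds`` and
    ``valid`` flags; ``valid`` means inside the extent and non-nodata in every
    layer.  No interpolation is performed — each point takes the value of the
    cell containing it, which keeps nodata boundaries crisp.
    """
    n = len(points)
    cols = {name: np.full(n, np.nan) for name in stack.names}
    in_bounds = np.zeros(n, dtype=bool)
    for i, pt in enumerate(points):
        loc = stack.grid.locate(pt.lon_deg, pt.lat_deg)
        if loc is None:
            continue
        in_bounds[i] = True
        r, c = loc
        for lyr in stack.layers:
            cols[lyr.name][i] = lyr.values[r, c]
    df = pd.DataFrame(cols)
    df["in_bounds"] = in_bounds
    df["valid"] = in_bounds & ~df[stack.names].isna().any(axis=1).to_numpy()
    return df


# ---------------------------------------------------------------------------
# Areas on the authalic sphere
# ---------------------------------------------------------------------------

def cell_band_area_km2(grid: LatLonGrid, row: int) -> float:
    """Area (km²) of one cell in the given row.

    area = R² · Δλ · (sin φ_top − sin φ_bottom) on the authalic sphere;
    identical for every cell of the row.
    """
    if not (0 <= row < grid.n_rows):
        raise IndexError(f"row {row} outside grid with {grid.n_rows} rows")
    lat_top = math.radians(grid.north_deg - row * grid.cell_deg)
    lat_bot = math.radians(grid.north_deg - (row + 1) * grid.cell_deg)
    dlon = math.radians(grid.cell_deg)
    return AUTHALIC_RADIUS_KM ** 2 * dlon * (math.sin(lat_top) - math.sin(lat_bot))


def cell_area_map_km2(grid: LatLonGrid) -> np.ndarray:
    """(n_rows, n_cols) array of cell areas in km²."""
    rows = np.arange(grid.n_rows)
    lat_top = np.radians(grid.north_deg - rows * grid.cell_deg)
    lat_bot = np.radians(grid.north_deg - (rows + 1) * grid.cell_deg)
    dlon = math.radians(grid.cell_deg)
    band = AUTHALIC_RADIUS_KM ** 2 * dlon * (np.sin(lat_top) - np.sin(lat_bot))
    return np.repeat(band[:, None], grid.n_cols, axis=1)


# ---------------------------------------------------------------------------
# Geodesics
# ---------------------------------------------------------------------------

def great_circle_km(a: GeoPoint, b: GeoPoint, radius_km: float = AUTHALIC_RADIUS_KM) -> float:
    """Spherical great-circle distance (haversine)."""
    phi1, phi2 = math.radians(a.lat_deg), math.radians(b.lat_deg)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon_deg - a.lon_deg)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(h)))


def _vincenty_inverse(a: GeoPoint, b: GeoPoint) -> tuple[float, float] | None:
    """WGS84 inverse problem: (distance_km, initial_bearing_deg), or None if the
    iteration fails to converge (nearly antipodal points)."""
    if a.lon_deg == b.lon_deg and a.lat_deg == b.lat_deg:
        return 0.0, 0.0
    L = math.radians(b.lon_deg - a.lon_deg)
    U1 = math.atan((1 - _WGS84_F) * math.tan(math.radians(a.lat_deg)))
    U2 = math.atan((1 - _WGS84_F) * math.tan(math.radians(b.lat_deg)))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam,
                               cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0, 0.0  # coincident
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha ** 2
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = _WGS84_F / 16.0 * cos2_alpha * (4.0 + _WGS84_F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * _WGS84_F * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)))
        if abs(lam - lam_prev) < 1e-12:
            break
    else:
        return None

    u2 = cos2_alpha * (_WGS84_A ** 2 - _WGS84_B ** 2) / _WGS84_B ** 2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
            - B / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma ** 2)
            * (-3.0 + 4.0 * cos_2sigma_m ** 2)))
    dist_km = _WGS84_B * A * (sigma - delta_sigma) / 1000.0
    bearing = math.degrees(math.atan2(
        cosU2 * math.sin(lam), cosU1 * sinU2 - sinU1 * cosU2 * math.cos(lam)))
    return dist_km, bearing % 360.0


def geodesic_km(a: GeoPoint, b: GeoPoint) -> float:
    """WGS84 ellipsoidal distance in km (Vincenty inverse).

    Falls back to the spherical great-circle for the rare nearly-antipodal
    pairs where the Vincenty iteration does not converge (with a warning).
    """
    res = _vincenty_inverse(a, b)
    if res is None:
        warnings.warn(
            "Vincenty iteration did not converge (near-antipodal points); "
            "using spherical great-circle distance", RuntimeWarning, stacklevel=2)
        return great_circle_km(a, b)
    return res[0]


def initial_bearing_deg(a: GeoPoint, b: GeoPoint) -> float:
    """Initial geodesic bearing a→b, degrees clockwise from north in [0, 360)."""
    if a.lon_deg == b.lon_deg and a.lat_deg == b.lat_deg:
        raise ValueError("bearing undefined for coincident points")
    res = _vincenty_inverse(a, b)
    if res is not None:
        return res[1]
    # spherical fallback
    phi1, phi2 = math.radians(a.lat_deg), math.radians(b.lat_deg)
    dlam = math.radians(b.lon_deg - a.lon_deg)
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    return math.degrees(math.atan2(y, x)) % 360.0


_COMPASS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def compass8(a: GeoPoint, b: GeoPoint) -> str:
    """Bucket the initial bearing a→b into 8 sectors of 45° centered on the
    cardinal/intercardinal directions (N covers 337.5°–22.5°, etc.)."""
    bearing = initial_bearing_deg(a, b)
    return _COMPASS[int(round(bearing / 45.0)) % 8]


# ---------------------------------------------------------------------------
# Coordinate parsing
# ---------------------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*(?P<deg>\d+(?:\.\d+)?)\s*[°d]\s*
        (?:(?P<min>\d+(?:\.\d+)?)\s*[′'m]\s*)?
        (?:(?P<sec>\d+(?:\.\d+)?)\s*[″"s]\s*)?
        (?P<hemi>[NSEW])\s*$""",
    re.VERBOSE | re.IGNORECASE,
)


def dms_to_decimal(text: str) -> float:
    """Convert ``109°23′53″E``-style degree/minute/second text to decimal degrees.

    W and S hemispheres are negative; minutes or seconds ≥ 60 are a parse error.
    """
    m = _DMS_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse DMS coordinate: {text!r}")
    deg = float(m.group("deg"))
    minutes = float(m.group("min") or 0.0)
    seconds = float(m.group("sec") or 0.0)
    if minutes >= 60.0:
        raise ValueError(f"minutes must be < 60 in {text!r}")
    if seconds >= 60.0:
        raise ValueError(f"seconds must be < 60 in {text!r}")
    value = deg + minutes / 60.0 + seconds / 3600.0
    if m.group("hemi").upper() in ("W", "S"):
        value = -value
    return value
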
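"""Habitat classification, area accounting, scenario change matrices and
centroid-migration tracking.

Suitability p ∈ [0, 1] is binned into four classes with boundaries belonging
to the lower class: non-suitable (p ≤ 0.2), low (0.2 < p ≤ 0.4), medium
(0.4 < p ≤ 0.6) and high (p > 0.6).  Areas are cell sums of the spherical
band formula (authalic sphere), reported in units of 10⁴ km² to two decimals
as is conventional in range-shift tables; raw km² are kept internally.

For scenario-to-scenario change and for centroids, "suitable" means p above
the non-suitable cutoff (default 0.2, i.e. all three suitable classes); the
change rates (loss/increase/retention) are percentages of the *baseline*
total suitable area, so retention + loss = 100 exactly before rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import (GeoPoint, GridMismatchError, LatLonGrid, RasterLayer,
                  cell_area_map_km2, compass8, geodesic_km)

__all__ = ["ClassificationScheme", "SuitabilityClasses", "AreaReport",
           "ChangeReport", "CentroidTrack", "classify", "class_areas",
           "change_matrix", "change_rates", "centroid", "migration_track"]

CLASS_LABELS = ("non", "low", "medium", "high")


@dataclass(frozen=True)
class ClassificationScheme:
    """Three thresholds splitting [0, 1] into non/low/medium/high."""

    t1: float = 0.2
    t2: float = 0.4
    t3: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 < self.t1 < self.t2 < self.t3 < 1.0):
            raise ValueError("thresholds must satisfy 0 < t1 < t2 < t3 < 1")


@dataclass
class SuitabilityClasses:
    """Integer class map: 0=non, 1=low, 2=medium, 3=high; -1 marks nodata."""

    grid: LatLonGrid
    codes: np.ndarray
    scheme: ClassificationScheme

    def to_layer(self, name: str = "suitability_class") -> RasterLayer:
        vals = np.where(self.codes < 0, np.nan, self.codes.astype(float))
        return RasterLayer(grid=self.grid, name=name, values=vals)


def classify(p_map: RasterLayer,
             scheme: ClassificationScheme = ClassificationScheme()) -> SuitabilityClasses:
    """Bin a suitability map into the four classes (boundaries to the lower class)."""
    p = p_map.values
    finite = np.isfinite(p)
    if finite.any() and ((p[finite] < 0) | (p[finite] > 1)).any():
        bad = p[finite]
        bad = bad[(bad < 0) | (bad > 1)][0]
        raise ValueError(f"suitability value {bad} outside [0, 1]")
    codes = np.full(p.shape, -1, dtype=int)
    codes[finite & (p <= scheme.t1)] = 0
    codes[finite & (p > scheme.t1) & (p <= scheme.t2)] = 1
    codes[finite & (p > scheme.t2) & (p <= scheme.t3)] = 2
    codes[finite & (p > scheme.t3)] = 3
    return SuitabilityClasses(grid=p_map.grid, codes=codes, scheme=scheme)


@dataclass
class AreaReport:
    """Per-class suitable areas; `*_1e4km2` properties report the printed units."""

    lsda_km2: float
    msda_km2: float
    hsda_km2: float
    non_km2: float

    @property
    def tsda_km2(self) -> float:
        return self.lsda_km2 + self.msda_km2 + self.hsda_km2

    @property
    def lsda(self) -> float:
        return round(self.lsda_km2 / 1e4, 2)

    @property
    def msda(self) -> float:
        return round(self.msda_km2 / 1e4, 2)

    @property
    def hsda(self) -> float:
        return round(self.hsda_km2 / 1e4, 2)

    @property
    def tsda(self) -> float:
        return round(self.tsda_km2 / 1e4, 2)

    @property
    def hsda_tsda_ratio(self) -> float:
        """High-suitable share of the total suitable area, to 2 d.p."""
        if self.tsda_km2 == 0:
            return float("nan")
        return round(self.hsda_km2 / self.tsda_km2, 2)

    @classmethod
    def from_printed(cls, lsda: float, msda: float, hsda: float) -> "AreaReport":
        """Build from class areas already in 10⁴ km² (e.g. a published table)."""
        return cls(lsda_km2=lsda * 1e4, msda_km2=msda * 1e4,
                   hsda_km2=hsda * 1e4, non_km2=0.0)

    def to_dict(self) -> dict:
        return {"LSDA": self.lsda, "MSDA": self.msda, "HSDA": self.hsda,
                "TSDA": self.tsda, "HSDA/TSDA": self.hsda_tsda_ratio,
                "LSDA_km2": self.lsda_km2, "MSDA_km2": self.msda_km2,
                "HSDA_km2": self.hsda_km2, "TSDA_km2": self.tsda_km2,
                "non_km2": self.non_km2}


def class_areas(classes: SuitabilityClasses) -> AreaReport:
    """Sum spherical cell areas per class."""
    areas = cell_area_map_km2(classes.grid)
    def tot(code: int) -> float:
        return float(areas[classes.codes == code].sum())
    return AreaReport(lsda_km2=tot(1), msda_km2=tot(2), hsda_km2=tot(3),
                      non_km2=tot(0))


@dataclass
class ChangeReport:
    """Reserved/lost/new accounting between a baseline and a future map.

    Rates are percentages of the baseline total suitable area, to 2 d.p.
    """

    reserved_km2: float
    lost_km2: float
    new_km2: float
    nsda_km2: float
    baseline_tsda_km2: float

    @property
    def reserved(self) -> float:
        return round(self.reserved_km2 / 1e4, 2)

    @property
    def lost(self) -> float:
        return round(self.lost_km2 / 1e4, 2)

    @property
    def new(self) -> float:
        return round(self.new_km2 / 1e4, 2)

    @property
    def nsda(self) -> float:
        return round(self.nsda_km2 / 1e4, 2)

    @property
    def loss_rate(self) -> float:
        return round(100.0 * self.lost_km2 / self.baseline_tsda_km2, 2)

    @property
    def increase_rate(self) -> float:
        return round(100.0 * self.new_km2 / self.baseline_tsda_km2, 2)

    @property
    def retention_rate(self) -> float:
        return round(100.0 * self.reserved_km2 / self.baseline_tsda_km2, 2)

    def to_dict(self) -> dict:
        return {"reserved": self.reserved, "lost": self.lost, "new": self.new,
                "nsda": self.nsda, "loss_rate": self.loss_rate,
                "increase_rate": self.increase_rate,
                "retention_rate": self.retention_rate,
                "reserved_km2": self.reserved_km2, "lost_km2": self.lost_km2,
                "new_km2": self.new_km2, "nsda_km2": self.nsda_km2,
                "baseline_tsda_km2": self.baseline_tsda_km2}


def change_matrix(baseline: RasterLayer, future: RasterLayer,
                  cutoff: float = 0.2,
                  baseline_tsda_km2: float | None = None) -> ChangeReport:
    """Cross-tabulate suitable (p > cutoff) cells between two scenarios.

    reserved = suitable in both; lost = baseline only; new = future only;
    nsda = suitable in neither (valid cells).  The rate denominator defaults
    to the baseline suitable area (reserved + lost).
    """
    if baseline.grid != future.grid:
        raise GridMismatchError("baseline and future maps are on different grids")
    b = baseline.values > cutoff
    f = future.values > cutoff
    valid = np.isfinite(baseline.values) & np.isfinite(future.values)
    areas = cell_area_map_km2(baseline.grid)
    reserved = float(areas[valid & b & f].sum())
    lost = float(areas[valid & b & ~f].sum())
    new = float(areas[valid & ~b & f].sum())
    nsda = float(areas[valid & ~b & ~f].sum())
    if baseline_tsda_km2 is None:
        baseline_tsda_km2 = reserved + lost
    return ChangeReport(reserved_km2=reserved, lost_km2=lost, new_km2=new,
                        nsda_km2=nsda, baseline_tsda_km2=baseline_tsda_km2)


def change_rates(reserved_km2: float, lost_km2: float, new_km2: float,
                 baseline_tsda_km2: float) -> dict[str, float]:
    """Loss/increase/retention rates (%) over a shared baseline denominator."""
    if baseline_tsda_km2 <= 0:
        raise ValueError("baseline total suitable area must be positive")
    return {
        "loss_rate": round(100.0 * lost_km2 / baseline_tsda_km2, 2),
        "increase_rate": round(100.0 * new_km2 / baseline_tsda_km2, 2),
        "retention_rate": round(100.0 * reserved_km2 / baseline_tsda_km2, 2),
    }


def centroid(p_map: RasterLayer, cutoff: float = 0.2,
             weight_by_p: bool = False) -> GeoPoint:
    """Area-weighted center of the suitable (p > cutoff) region.

    By default each suitable cell is weighted by its spherical area (binary
    mask); ``weight_by_p`` additionally weights by the suitability value.
    """
    grid = p_map.grid
    mask = np.isfinite(p_map.values) & (p_map.values > cutoff)
    if not mask.any():
        raise ValueError(f"no cell exceeds the suitability cutoff {cutoff}")
    areas = cell_area_map_km2(grid)
    w = areas * mask
    if weight_by_p:
        w = w * np.nan_to_num(p_map.values)
    lon = np.broadcast_to(grid.lon_centers()[None, :], w.shape)
    lat = np.broadcast_to(grid.lat_centers()[:, None], w.shape)
    total = w.sum()
    return GeoPoint(float((w * lon).sum() / total), float((w * lat).sum() / total))


@dataclass
class CentroidTrack:
    """Per-scenario centroid with geodesic distance/bearing from the baseline."""

    table: pd.DataFrame  # columns: scenario, lon, lat, km_from_baseline, direction
    baseline: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def migration_track(p_maps: dict[str, RasterLayer], baseline: str,
                    cutoff: float = 0.2, weight_by_p: bool = False) -> CentroidTrack:
    """Centroid per scenario plus distance (km) and compass direction from the
    baseline centroid; scenarios with no suitable cell are flagged with NaNs."""
    if baseline not in p_maps:
        raise ValueError(f"baseline scenario {baseline!r} missing from maps")
    base_pt = centroid(p_maps[baseline], cutoff, weight_by_p)
    rows = []
    for label, layer in p_maps.items():
        try:
            pt = centroid(layer, cutoff, weight_by_p)
        except ValueError:
            rows.append({"scenario": label, "lon": np.nan, "lat": np.nan,
                         "km_from_baseline": np.nan, "direction": ""})
            continue
        if label == baseline:
            dist, direction = 0.0, ""
        else:
            dist = geodesic_km(base_pt, pt)
            same = (pt.lon_deg == base_pt.lon_deg and pt.lat_deg == base_pt.lat_deg)
            direction = "" if same else compass8(base_pt, pt)
        rows.append({"scenario": label, "lon": pt.lon_deg, "lat": pt.lat_deg,
                     "km_from_baseline": dist, "direction": direction})
    return CentroidTrack(table=pd.DataFrame(rows), baseline=baseline)
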
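"""Presence-record cleaning and spatial thinning.

Presence-only records downloaded from aggregators are typically full of exact
duplicates and spatial clusters around herbaria and cities.  This module
collapses duplicates, drops impossible coordinates, and enforces a minimum
pairwise distance between retained records (default 10 km) so that no local
cluster dominates the model's presence sample.

Thinning rule: records strictly closer than ``min_km`` (great-circle) to an
already-retained record are dropped during one greedy pass over a seeded
random permutation of the records.  Records *exactly* ``min_km`` apart are
both retainable ("less than" is strict).  The pass guarantees the minimum
pairwise distance; the seeded shuffle makes which cluster member survives
random but reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import AUTHALIC_RADIUS_KM, GeoPoint, RasterStack, extract_values

__all__ = ["OccurrenceRecord", "OccurrenceSet", "EmptyOccurrenceError",
           "clean", "thin", "read_occurrences_csv", "write_occurrences_csv"]

logger = logging.getLogger(__name__)


class EmptyOccurrenceError(ValueError):
    """Raised when cleaning/filtering leaves no usable records."""


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    location: GeoPoint
    source_id: str | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")


@dataclass
class OccurrenceSet:
    """A list of presence records plus the thinning parameters applied to it."""

    records: list[OccurrenceRecord]
    thinning_min_km: float | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def points(self) -> list[GeoPoint]:
        return [r.location for r in self.records]

    def lonlat(self) -> np.ndarray:
        """(n, 2) array of [lon, lat]."""
        return np.array([[r.location.lon_deg, r.location.lat_deg]
                         for r in self.records], dtype=float).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": [r.species for r in self.records],
            "longitude": [r.location.lon_deg for r in self.records],
            "latitude": [r.location.lat_deg for r in self.records],
            "source_id": [r.source_id for r in self.records],
        })


def _pairwise_gc_km(lonlat: np.ndarray) -> np.ndarray:
    """Dense great-circle distance matrix (km) on the authalic sphere."""
    lon = np.radians(lonlat[:, 0])[:, None]
    lat = np.radians(lonlat[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * AUTHALIC_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def clean(records: list[OccurrenceRecord] | pd.DataFrame,
          mask_stack: RasterStack | None = None) -> OccurrenceSet:
    """Collapse exact duplicates and drop invalid/raster-nodata records.

    Parameters
    ----------
    records
        Parsed records, or a DataFrame with ``species, longitude, latitude``
        (and optional ``source_id``) columns; rows with out-of-range
        coordinates are dropped with a logged count rather than raising.
    mask_stack
        Optional raster stack; records falling outside its extent or on a
        nodata cell are dropped (mirrors clipping occurrences to the climate
        grids before modelling).
    """
    if isinstance(records, pd.DataFrame):
        rows = []
        n_invalid = 0
        for _, row in records.iterrows():
            try:
                rows.append(OccurrenceRecord(
                    species=str(row["species"]),
                    location=GeoPoint(float(row["longitude"]), float(row["latitude"])),
                    source_id=(str(row["source_id"])
                               if "source_id" in row and pd.notna(row.get("source_id"))
                               else None),
                ))
            except (ValueError, TypeError):
                n_invalid += 1
        records = rows
    else:
        n_invalid = 0
        records = list(records)

    seen: set[tuple[str, float, float]] = set()
    unique: list[OccurrenceRecord] = []
    n_dups = 0
    for rec in records:
        key = (rec.species, rec.location.lon_deg, rec.location.lat_deg)
        if key in seen:
            n_dups += 1
            continue
        seen.add(key)
        unique.append(rec)

    n_nodata = 0
    if mask_stack is not None and unique:
        flags = extract_values(mask_stack, [r.location for r in unique])["valid"]
        kept = [r for r, ok in zip(unique, flags) if ok]
        n_nodata = len(unique) - len(kept)
        unique = kept

    logger.info("clean: %d in, %d invalid, %d duplicate, %d on nodata, %d out",
                len(records) + n_invalid, n_invalid, n_dups, n_nodata, len(unique))
    if not unique:
        raise EmptyOccurrenceError("no records survive cleaning")
    return OccurrenceSet(records=unique)


def thin(occ: OccurrenceSet, min_km: float = 10.0, seed: int = 0) -> OccurrenceSet:
    """Greedy spatial thinning to a strict minimum pairwise distance.

    Visits the records in a seeded random order; a record is retained iff no
    already-retained record lies strictly closer than ``min_km``
    (great-circle, authalic sphere).  Idempotent for a fixed seed.
    """
    n = len(occ.records)
    if n == 0:
        raise EmptyOccurrenceError("cannot thin an empty occurrence set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    dist = _pairwise_gc_km(occ.lonlat())

    retained_idx: list[int] = []
    tol = 1e-9  # float slack so pairs at exactly min_km are both retainable
    for i in order:
        if all(dist[i, j] >= min_km - tol for j in retained_idx):
            retained_idx.append(i)
    retained_idx.sort()  # preserve input ordering in the output
    logger.info("thin: %d in -> %d retained (min_km=%.3g, seed=%d)",
                n, len(retained_idx), min_km, seed)
    return OccurrenceSet(records=[occ.records[i] for i in retained_idx],
                         thinning_min_km=min_km, seed=seed)


def read_occurrences_csv(path) -> pd.DataFrame:
    """Read an occurrence CSV (``species,longitude,latitude[,source_id]``)."""
    df = pd.read_csv(path)
    missing = {"species", "longitude", "latitude"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    return df


def write_occurrences_csv(occ: OccurrenceSet, path) -> None:
    df = occ.to_frame()
    if df["source_id"].isna().all():
        df = df.drop(columns="source_id")
    df.to_csv(path, index=False)
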
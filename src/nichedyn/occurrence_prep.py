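"""Occurrence-record cleaning and spatial rarefaction.

Raw occurrence tables (taxon, lon, lat, optional coordinate uncertainty in
km) are filtered for coordinate validity and positional uncertainty,
deduplicated on exact coordinates, and then spatially thinned so that no two
retained records lie within a chosen great-circle radius of each other.
Thinning reduces sampling bias and spatial autocorrelation before any
environment-space or distribution modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import EARTH_RADIUS_KM

logger = logging.getLogger(__name__)

DEFAULT_MAX_UNCERTAINTY_KM = 10.0
DEFAULT_RAREFY_RADIUS_KM = 10.0

COLUMNS = ["taxon", "lon", "lat", "uncertainty_km"]


@dataclass
class OccurrenceSet:
    """Ordered occurrence records for one taxon, with provenance stage tags.

    ``records`` is a DataFrame with columns taxon, lon, lat, uncertainty_km
    (uncertainty may be NaN when unreported).
    """

    taxon: str
    records: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if "uncertainty_km" in missing:
            self.records = self.records.assign(uncertainty_km=np.nan)
            missing.remove("uncertainty_km")
        if missing:
            raise ValueError(f"occurrence table missing columns: {missing}")
        self.records = self.records[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        return self.records[["lon", "lat"]].to_numpy(dtype=float)

    def tagged(self, tag: str, records: pd.DataFrame) -> "OccurrenceSet":
        return OccurrenceSet(self.taxon, records, self.provenance + [tag])


def read_occurrences(path: str | Path, taxon: str | None = None) -> OccurrenceSet:
    """Read an occurrence CSV (columns taxon, lon, lat[, uncertainty_km])."""
    df = pd.read_csv(path)
    if taxon is not None:
        df = df[df["taxon"] == taxon]
        name = taxon
    else:
        taxa = df["taxon"].unique()
        if len(taxa) != 1:
            raise ValueError(
                f"CSV contains {len(taxa)} taxa; pass taxon= to select one"
            )
        name = taxa[0]
    return OccurrenceSet(name, df, provenance=[f"read:{Path(path).name}"])


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.records.to_csv(path, index=False)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km. Broadcasts."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def clean_records(
    raw: OccurrenceSet, max_uncertainty_km: float = DEFAULT_MAX_UNCERTAINTY_KM
) -> OccurrenceSet:
    """Drop out-of-bounds coordinates, high-uncertainty records, and exact duplicates.

    Records whose positional uncertainty exceeds ``max_uncertainty_km`` are
    removed; records with *missing* uncertainty are retained (unknown is not
    evidence of imprecision, and most aggregated records lack the field).
    Duplicate (lon, lat) pairs keep the first record in input order.
    Out-of-bounds coordinates are rejected per record and logged, not fatal.
    """
    if max_uncertainty_km <= 0:
        raise ValueError("max_uncertainty_km must be positive")
    df = raw.records
    in_bounds = (
        df["lon"].between(-180.0, 180.0)
        & df["lat"].between(-90.0, 90.0)
        & df["lon"].notna()
        & df["lat"].notna()
    )
    n_oob = int((~in_bounds).sum())
    if n_oob:
        logger.warning("%s: rejected %d out-of-bounds records", raw.taxon, n_oob)
    df = df[in_bounds]
    unc_ok = df["uncertainty_km"].isna() | (df["uncertainty_km"] <= max_uncertainty_km)
    df = df[unc_ok]
    df = df.drop_duplicates(subset=["lon", "lat"], keep="first")
    logger.info("%s: %d records after cleaning (from %d)", raw.taxon, len(df), len(raw))
    return raw.tagged(f"clean:max_unc={max_uncertainty_km}", df.reset_index(drop=True))


def rarefy(
    occ: OccurrenceSet,
    radius_km: float = DEFAULT_RAREFY_RADIUS_KM,
    seed: int = 0,
) -> OccurrenceSet:
    """Spatially thin records so all pairwise great-circle distances >= radius_km.

    Greedy retention over a seeded random scan order: a record is kept iff it
    lies at least ``radius_km`` from every record already kept. The result is
    maximal — every dropped record conflicts with some kept one. Output rows
    keep their original input order.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    n = len(occ)
    if n == 0:
        return occ.tagged(f"rarefy:r={radius_km},seed={seed}", occ.records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    coords = occ.coords
    kept: list[int] = []
    for i in order:
        lon, lat = coords[i]
        if kept:
            d = haversine_km(lon, lat, coords[kept, 0], coords[kept, 1])
            if np.any(d < radius_km):
                continue
        kept.append(int(i))
    kept.sort()
    logger.info("%s: %d records after rarefaction (from %d)", occ.taxon, len(kept), n)
    return occ.tagged(
        f"rarefy:r={radius_km},seed={seed}", occ.records.iloc[kept].reset_index(drop=True)
    )
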
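"""Natural migratory direction from ring recoveries.

Bearings and great-circle distances from ringing sites to recovery
sites, filtered to same-year autumn recoveries (found September to
November, ringed late May to August) farther than 250 km — the distance
floor avoids directional bias from a surplus of nearby recoveries. The
circular mean of the retained bearings, with a Rayleigh test of
uniformity, estimates the population's natural autumn direction.

Spherical Earth, radius 6371.0 km: bearing errors against an ellipsoid
are far below the precision of any orientation analysis.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import normalize_angle
from .circstats import CircSummary, RayleighResult, circ_mean_r, rayleigh_test

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "RecoveryRecord",
    "initial_bearing",
    "gc_distance",
    "destination_point",
    "filter_recoveries",
    "natural_direction",
    "read_recoveries_csv",
    "bearings_frame",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    lat: float
    lon: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of range")


@dataclass(frozen=True)
class RecoveryRecord:
    """One ring recovery; distance and bearing are always recomputed
    from the coordinates, never trusted from the input table."""

    ring_id: str
    ring_date: _dt.date
    find_date: _dt.date
    ring_point: GeoPoint
    find_point: GeoPoint

    @property
    def distance_km(self) -> float:
        return gc_distance(self.ring_point, self.find_point)

    @property
    def bearing(self) -> float:
        return initial_bearing(self.ring_point, self.find_point)


def _rad(p: GeoPoint):
    return np.deg2rad(p.lat), np.deg2rad(p.lon)


def initial_bearing(origin: GeoPoint, dest: GeoPoint) -> float:
    """Initial great-circle bearing from origin to dest, degrees
    clockwise from geographic North.

    theta = atan2(sin(dlon) cos(lat2),
                  cos(lat1) sin(lat2) - sin(lat1) cos(lat2) cos(dlon))
    """
    if gc_distance(origin, dest) < 1e-9:
        raise ValueError("bearing undefined for coincident points")
    if abs(gc_distance(origin, dest) - np.pi * EARTH_RADIUS_KM) < 1e-6:
        raise ValueError("bearing undefined for antipodal points")
    p1, l1 = _rad(origin)
    p2, l2 = _rad(dest)
    dl = l2 - l1
    theta = np.arctan2(
        np.sin(dl) * np.cos(p2),
        np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl),
    )
    return normalize_angle(float(np.rad2deg(theta)))


def gc_distance(origin: GeoPoint, dest: GeoPoint) -> float:
    """Haversine great-circle distance in km (sphere, R = 6371 km)."""
    p1, l1 = _rad(origin)
    p2, l2 = _rad(dest)
    a = (
        np.sin((p2 - p1) / 2.0) ** 2
        + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def destination_point(origin: GeoPoint, bearing_deg: float, distance_km: float) -> GeoPoint:
    """Spherical forward problem: travel from origin along an initial
    bearing for a great-circle distance."""
    p1, l1 = _rad(origin)
    d = distance_km / EARTH_RADIUS_KM
    b = np.deg2rad(bearing_deg)
    p2 = np.arcsin(np.sin(p1) * np.cos(d) + np.cos(p1) * np.sin(d) * np.cos(b))
    l2 = l1 + np.arctan2(
        np.sin(b) * np.sin(d) * np.cos(p1),
        np.cos(d) - np.sin(p1) * np.sin(p2),
    )
    lon = (np.rad2deg(l2) + 180.0) % 360.0 - 180.0
    return GeoPoint(lat=float(np.rad2deg(p2)), lon=float(lon))


def _in_ring_window(d: _dt.date, late_may_day: int) -> bool:
    return (d.month == 5 and d.day >= late_may_day) or d.month in (6, 7, 8)


def filter_recoveries(
    records,
    min_distance_km: float = 250.0,
    late_may_day: int = 21,
) -> list[RecoveryRecord]:
    """Keep same-year autumn recoveries of breeding-season ringings.

    Kept iff ringed late May (day >= ``late_may_day``) through August,
    found September–November of the same calendar year, and recovered
    strictly farther than ``min_distance_km`` from the ringing site.
    Idempotent.
    """
    kept = []
    for rec in records:
        try:
            if not _in_ring_window(rec.ring_date, late_may_day):
                continue
            if rec.find_date.month not in (9, 10, 11):
                continue
            if rec.find_date.year != rec.ring_date.year:
                continue
            if rec.distance_km <= min_distance_km:
                continue
        except (ValueError, AttributeError) as exc:
            warnings.warn(f"skipping malformed record {rec!r}: {exc}", stacklevel=2)
            continue
        kept.append(rec)
    return kept


def natural_direction(
    records, declination_deg: float = 0.0, prefiltered: bool = False
) -> tuple[CircSummary, RayleighResult]:
    """Circular mean and Rayleigh test of recovery bearings.

    ``declination_deg`` is added to each geographic bearing to express
    directions relative to magnetic North (default 0: geographic).
    """
    recs = list(records) if prefiltered else filter_recoveries(records)
    if len(recs) < 2:
        raise ValueError("need at least 2 recovery records after filtering")
    bearings = [normalize_angle(r.bearing + declination_deg) for r in recs]
    summ = circ_mean_r(bearings)
    return summ, rayleigh_test(summ.n, summ.r)


def read_recoveries_csv(path) -> list[RecoveryRecord]:
    """Read recoveries.csv (ring_id, ring_date, ring_lat, ring_lon,
    find_date, find_lat, find_lon; ISO 8601 dates, decimal degrees)."""
    df = pd.read_csv(path)
    required = [
        "ring_id", "ring_date", "ring_lat", "ring_lon",
        "find_date", "find_lat", "find_lon",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"recoveries table missing required column(s): {missing}")
    out = []
    for _, row in df.iterrows():
        try:
            out.append(
                RecoveryRecord(
                    ring_id=str(row["ring_id"]),
                    ring_date=_dt.date.fromisoformat(str(row["ring_date"])),
                    find_date=_dt.date.fromisoformat(str(row["find_date"])),
                    ring_point=GeoPoint(float(row["ring_lat"]), float(row["ring_lon"])),
                    find_point=GeoPoint(float(row["find_lat"]), float(row["find_lon"])),
                )
            )
        except ValueError as exc:
            warnings.warn(f"skipping row {row['ring_id']!r}: {exc}", stacklevel=2)
    return out


def bearings_frame(records, kept: list[RecoveryRecord]) -> pd.DataFrame:
    """Per-record bearing table with keep/drop provenance
    (bearings.tsv schema)."""
    kept_ids = {id(r) for r in kept}
    rows = []
    for rec in records:
        reason = ""
        if id(rec) not in kept_ids:
            if not _in_ring_window(rec.ring_date, 21):
                reason = "ringing_outside_window"
            elif rec.find_date.month not in (9, 10, 11):
                reason = "recovery_outside_autumn"
            elif rec.find_date.year != rec.ring_date.year:
                reason = "different_year"
            else:
                reason = "too_close"
        rows.append(
            dict(
                ring_id=rec.ring_id,
                distance_km=round(rec.distance_km, 2),
                bearing_deg=round(rec.bearing, 2),
                kept=int(id(rec) in kept_ids),
                drop_reason=reason,
            )
        )
    return pd.DataFrame(rows)
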
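"""Residence inference and three-tier exposure-group classification.

Residence is the modal nighttime (around 04:00) GPS location during the
baseline period, on a rounded coordinate grid; participants without
qualifying GPS fall back to their enrollment hometown.  Exposure groups are
defined by great-circle distance from a conflict reference point:
< 60 km high, 60-110 km medium (both boundaries inclusive), > 110 km low.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError
from .studycal import StudyCalendar

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: Default conflict reference coordinate (Gaza City centroid).
DEFAULT_REFERENCE = (31.5017, 34.4668)

#: Default clock window interpreting "around 04:00": [03:30, 04:30).
DEFAULT_NIGHT_WINDOW = (3.5, 4.5)


def _check_coord(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise ConfigurationError(f"invalid coordinate ({lat}, {lon})")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points.

    Spherical Earth of radius 6371.0 km; symmetric, nonnegative, zero iff the
    points coincide (up to floating-point tolerance).
    """
    _check_coord(*a)
    _check_coord(*b)
    phi1, phi2 = math.radians(a[0]), math.radians(b[0])
    dphi = phi2 - phi1
    dlam = math.radians(b[1] - a[1])
    h = (math.sin(dphi / 2.0) ** 2
         + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def classify_exposure(distance_km: float) -> str:
    """Map distance from the reference point to {high, medium, low}.

    Strictly below 60 km is high; 60 km and 110 km inclusive are medium;
    above 110 km is low.
    """
    if distance_km < 0 or not math.isfinite(distance_km):
        raise ConfigurationError(f"invalid distance {distance_km!r}")
    if distance_km < 60.0:
        return "high"
    if distance_km <= 110.0:
        return "medium"
    return "low"


@dataclass
class ExposureAssignment:
    participant_id: str
    residence_lat: float
    residence_lon: float
    source: str            # gps_mode | hometown_fallback
    distance_km: float
    group: str


def infer_residence(samples: pd.DataFrame, calendar: StudyCalendar,
                    night_window: tuple[float, float] = DEFAULT_NIGHT_WINDOW,
                    grid_precision: int = 3,
                    hometown: tuple[float, float] | None = None
                    ) -> tuple[tuple[float, float], str]:
    """Modal baseline-night grid cell of one participant's GPS, or the hometown.

    Samples are restricted to baseline-period dates and the night clock
    window; coordinates are rounded to ``grid_precision`` decimal degrees and
    the most frequent cell wins (ties by earliest-observed cell, logged).
    With no qualifying samples the enrollment hometown is returned with
    ``source='hometown_fallback'``; lacking that too is an error.
    """
    lo, hi = night_window
    if not (lo <= 4.0 < hi):
        raise ConfigurationError("night_window must contain 04:00")
    if len(samples):
        t = samples["timestamp"]
        hour = t.dt.hour + t.dt.minute / 60.0 + t.dt.second / 3600.0
        b_start, b_end = calendar.period_ranges["B"]
        date = t.dt.date
        sel = ((hour >= lo) & (hour < hi)
               & (date >= b_start) & (date <= b_end))
        night = samples.loc[sel]
    else:
        night = samples
    if len(night) == 0:
        if hometown is None:
            raise AnalysisError("no baseline-night GPS and no hometown")
        return hometown, "hometown_fallback"
    cells = list(zip(night["latitude"].round(grid_precision),
                     night["longitude"].round(grid_precision)))
    counts: dict[tuple[float, float], int] = {}
    for c in cells:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.values())
    winners = [c for c in counts if counts[c] == best]
    if len(winners) > 1:
        log.info("infer_residence: %d tied modal cells; keeping the "
                 "earliest-observed", len(winners))
    for c in cells:                      # earliest-observed tie-break
        if counts[c] == best:
            return c, "gps_mode"
    raise AssertionError("unreachable")


def assign_exposure(profiles: pd.DataFrame, gps: pd.DataFrame,
                    calendar: StudyCalendar,
                    reference: tuple[float, float] = DEFAULT_REFERENCE,
                    night_window: tuple[float, float] = DEFAULT_NIGHT_WINDOW,
                    grid_precision: int = 3) -> pd.DataFrame:
    """Exposure assignment table for a whole cohort.

    Output columns: participant_id, residence_lat, residence_lon, source,
    distance_km, group.  Distances within 5 km of a 60/110 km threshold are
    logged — they are sensitive to the choice of reference coordinate.
    """
    by_pid = dict(tuple(gps.groupby("participant_id"))) if len(gps) else {}
    empty = gps.iloc[0:0] if len(gps) else pd.DataFrame(
        columns=["participant_id", "timestamp", "latitude", "longitude"])
    rows = []
    for p in profiles.itertuples(index=False):
        hometown = None
        if np.isfinite(p.home_lat) and np.isfinite(p.home_lon):
            hometown = (p.home_lat, p.home_lon)
        (lat, lon), source = infer_residence(
            by_pid.get(p.participant_id, empty), calendar,
            night_window, grid_precision, hometown)
        d = haversine_km((lat, lon), reference)
        if abs(d - 60.0) < 5.0 or abs(d - 110.0) < 5.0:
            log.info("participant %s: distance %.1f km is near an exposure "
                     "threshold", p.participant_id, d)
        rows.append(ExposureAssignment(p.participant_id, lat, lon, source,
                                       d, classify_exposure(d)))
    return pd.DataFrame([r.__dict__ for r in rows])
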
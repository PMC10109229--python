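"""Siren-triggered heart-rate response statistic.

For each eligible siren and participant, the response is::

    delta = max bpm over [t-5 min, t+15 min]  -  mean bpm over [t-45, t-15) min

i.e. the peak around the siren minus the pre-siren baseline average.  Sirens
qualify only when sounded between 02:00 and 06:00 local time (minimizing
physical-activity confounding) and when no other siren of the same area falls
inside the baseline time frame.  Each participant is summarized by the mean
of their per-siren deltas; the cohort statistic is the median of those means.

Window conventions are fixed: the baseline window is half-open (a sample at
exactly t-15 min is excluded), the affected window closed (a sample at
exactly t+15 min is included).  Because the affected value is a maximum and
the baseline a mean, the statistic has a positive bias on impulse-free noisy
series; this is a property of the estimator, not corrected here.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import AnalysisError

log = logging.getLogger(__name__)

ELIGIBLE_HOURS = (2.0, 6.0)          # [02:00, 06:00) local clock
BASELINE_WINDOW_MIN = (-45.0, -15.0)  # [t-45, t-15)
AFFECTED_WINDOW_MIN = (-5.0, 15.0)    # [t-5,  t+15]
EXCLUSION_WINDOW_MIN = (-45.0, -15.0)  # open interval scanned for sibling sirens


def eligible_sirens(sirens: pd.DataFrame, area: str) -> pd.DataFrame:
    """Sirens of one area that pass the clock-time and isolation filters.

    Keeps sirens with local start time in [02:00, 06:00) for which no other
    siren of the same area falls strictly inside (t-45 min, t-15 min).
    """
    sub = sirens[sirens["area_id"] == area].sort_values("start_time")
    if sub.empty:
        return sub.reset_index(drop=True)
    times = sub["start_time"]
    hour = times.dt.hour + times.dt.minute / 60.0 + times.dt.second / 3600.0
    in_clock = (hour >= ELIGIBLE_HOURS[0]) & (hour < ELIGIBLE_HOURS[1])

    tvals = times.to_numpy()
    keep = []
    for i, t in enumerate(tvals):
        lo = t + np.timedelta64(int(EXCLUSION_WINDOW_MIN[0] * 60), "s")
        hi = t + np.timedelta64(int(EXCLUSION_WINDOW_MIN[1] * 60), "s")
        others = np.delete(tvals, i)
        keep.append(not np.any((others > lo) & (others < hi)))
    return sub[in_clock.to_numpy() & np.array(keep)].reset_index(drop=True)


def siren_delta(hr: pd.DataFrame, siren_time) -> dict | None:
    """Baseline mean / affected max / delta for one participant and siren.

    ``hr`` holds one participant's samples (timestamp, bpm).  Returns None
    (logged) when either window contains no sample.
    """
    t = pd.Timestamp(siren_time)
    ts = hr["timestamp"]
    base_sel = ((ts >= t + pd.Timedelta(minutes=BASELINE_WINDOW_MIN[0]))
                & (ts < t + pd.Timedelta(minutes=BASELINE_WINDOW_MIN[1])))
    aff_sel = ((ts >= t + pd.Timedelta(minutes=AFFECTED_WINDOW_MIN[0]))
               & (ts <= t + pd.Timedelta(minutes=AFFECTED_WINDOW_MIN[1])))
    if not base_sel.any() or not aff_sel.any():
        log.info("siren_delta: empty %s window for siren at %s; skipped",
                 "baseline" if not base_sel.any() else "affected", t)
        return None
    baseline = float(hr.loc[base_sel, "bpm"].mean())
    affected = float(hr.loc[aff_sel, "bpm"].max())
    return {"siren_time": t, "baseline_bpm": baseline,
            "affected_bpm": affected, "delta_bpm": affected - baseline,
            "n_baseline": int(base_sel.sum()), "n_affected": int(aff_sel.sum())}


def participant_mean_delta(responses: pd.DataFrame) -> pd.DataFrame:
    """Mean per-siren delta per participant (one row each)."""
    return (responses.groupby("participant_id", observed=True)["delta_bpm"]
            .agg(mean_delta_bpm="mean", n_sirens="size").reset_index())


def cohort_median(means: pd.DataFrame) -> float:
    """Median of the per-participant mean deltas (bpm)."""
    if len(means) == 0:
        raise AnalysisError("no eligible participants for the siren statistic")
    return float(means["mean_delta_bpm"].median())


def siren_response_analysis(heart_rate: pd.DataFrame, sirens: pd.DataFrame,
                            areas: pd.DataFrame) -> dict:
    """Full cohort siren analysis.

    ``areas`` maps participant_id -> area label (column ``group`` as produced
    by exposure classification, or any provided area column).  Returns the
    per-response table, the per-participant means, and the cohort median.
    """
    area_col = "group" if "group" in areas.columns else "area_id"
    area_of = dict(zip(areas["participant_id"], areas[area_col]))
    eligible_by_area = {a: eligible_sirens(sirens, a)
                        for a in pd.unique(areas[area_col])}
    rows = []
    for pid, hr in heart_rate.groupby("participant_id", observed=True):
        area = area_of.get(pid)
        if area is None:
            continue
        for ev in eligible_by_area[area].itertuples(index=False):
            resp = siren_delta(hr, ev.start_time)
            if resp is not None:
                rows.append({"participant_id": pid, **resp})
    responses = pd.DataFrame(rows)
    if responses.empty:
        raise AnalysisError("no siren responses could be computed")
    means = participant_mean_delta(responses)
    return {"responses": responses, "participant_means": means,
            "median_delta_bpm": cohort_median(means)}
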
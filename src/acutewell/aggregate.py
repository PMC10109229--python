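"""Period-weighted aggregation, inclusion filters, deltas and recovery flags.

Each participant x indicator x period collapses to a single weighted mean:
daily values are first averaged separately within work days and free days,
then combined as 5/7 * work + 2/7 * free, correcting for the unequal number
of free days across the short study periods.  A participant enters an
indicator's test only with at least one work-day and one free-day value in
every required period, so the analyzed n varies by indicator.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .studycal import PERIODS

log = logging.getLogger(__name__)

WORK_WEIGHT = 5.0 / 7.0
FREE_WEIGHT = 2.0 / 7.0


def period_aggregates(records: pd.DataFrame) -> pd.DataFrame:
    """Weighted period means for every participant x indicator x period.

    ``records`` is the labelled long table (participant_id, date, indicator,
    value, day_type, period).  Rows outside the four study periods are
    ignored.  The weighted mean is missing whenever either day-type component
    is missing.  Output columns: participant_id, indicator, period,
    work_mean, free_mean, weighted_mean.
    """
    df = records[records["period"].isin(PERIODS)]
    if df.empty:
        return pd.DataFrame(columns=["participant_id", "indicator", "period",
                                     "work_mean", "free_mean", "weighted_mean"])
    means = (df.groupby(["participant_id", "indicator", "period", "day_type"],
                        observed=True)["value"].mean().unstack("day_type"))
    for col in ("work", "free"):
        if col not in means.columns:
            means[col] = np.nan
    out = means.rename(columns={"work": "work_mean", "free": "free_mean"})
    out["weighted_mean"] = (WORK_WEIGHT * out["work_mean"]
                            + FREE_WEIGHT * out["free_mean"])
    return out.reset_index()[["participant_id", "indicator", "period",
                              "work_mean", "free_mean", "weighted_mean"]]


def weighted_period_mean(values_work, values_free) -> dict[str, float]:
    """Single-cell version of the 5/7-2/7 aggregate (mainly for inspection).

    Empty inputs yield missing components; the weighted mean is missing if
    either component is.
    """
    work = float(np.mean(values_work)) if len(values_work) else np.nan
    free = float(np.mean(values_free)) if len(values_free) else np.nan
    return {"work_mean": work, "free_mean": free,
            "weighted_mean": WORK_WEIGHT * work + FREE_WEIGHT * free}


def apply_inclusion_filter(aggregates: pd.DataFrame,
                           required_periods=PERIODS) -> dict[str, set]:
    """Eligible participant set per indicator.

    A participant is eligible for an indicator iff both the work-day and the
    free-day component are present in *every* required period.
    """
    required = list(required_periods)
    sub = aggregates[aggregates["period"].isin(required)].copy()
    sub["complete"] = sub["work_mean"].notna() & sub["free_mean"].notna()
    ok = (sub.groupby(["indicator", "participant_id"], observed=True)
          .agg(n_complete=("complete", "sum")))
    eligible = ok[ok["n_complete"] == len(required)].reset_index()
    out: dict[str, set] = {ind: set() for ind in aggregates["indicator"].unique()}
    for ind, grp in eligible.groupby("indicator", observed=True):
        out[ind] = set(grp["participant_id"])
    return out


def period_delta(aggregates: pd.DataFrame, p1: str, p2: str,
                 eligible: dict[str, set] | None = None) -> pd.DataFrame:
    """Per-participant weighted-mean difference ``p2 - p1`` per indicator.

    Participants missing either period's weighted mean are skipped (logged).
    If ``eligible`` is given, only those participants are considered.
    """
    wide = (aggregates.pivot_table(index=["participant_id", "indicator"],
                                   columns="period", values="weighted_mean",
                                   aggfunc="first", observed=True)
            .reset_index())
    for p in (p1, p2):
        if p not in wide.columns:
            wide[p] = np.nan
    if eligible is not None:
        keep = [pid in eligible.get(ind, set())
                for pid, ind in zip(wide["participant_id"], wide["indicator"])]
        wide = wide.loc[keep]
    n_missing = int((wide[p1].isna() | wide[p2].isna()).sum())
    if n_missing:
        log.info("period_delta(%s,%s): skipping %d participant-indicator "
                 "pairs with a missing period", p1, p2, n_missing)
    wide = wide.dropna(subset=[p1, p2])
    return pd.DataFrame({
        "participant_id": wide["participant_id"],
        "indicator": wide["indicator"],
        "delta": wide[p2] - wide[p1],
    }).reset_index(drop=True)


def flag_non_recovered(deltas: pd.DataFrame, adverse_sign: int,
                       k: float = 2.0) -> pd.DataFrame:
    """Flag participants whose B->R1 change stays adverse beyond k robust SDs.

    The cohort's delta distribution is summarized by its median and
    MAD * 1.4826 (a robust SD); a participant is flagged when the delta lies
    beyond ``median + adverse_sign * k * robust_sd`` in the adverse
    direction.  ``adverse_sign`` is +1 when an increase is adverse for the
    indicator, -1 when a decrease is.

    Refuses to flag fewer than 10 participants — the robust scale estimate
    is unstable below that.
    """
    if adverse_sign not in (+1, -1):
        raise AnalysisError("adverse_sign must be +1 or -1")
    if len(deltas) < 10:
        raise AnalysisError(
            f"refusing to flag with only {len(deltas)} participants (<10)")
    x = deltas["delta"].to_numpy(dtype=float)
    med = float(np.median(x))
    robust_sd = 1.4826 * float(np.median(np.abs(x - med)))
    if robust_sd == 0.0:
        # all-equal cohort: any deviation in the adverse direction is flagged
        flagged = adverse_sign * (x - med) > 0
    else:
        flagged = adverse_sign * (x - med) > k * robust_sd
    out = deltas.copy()
    out["flagged"] = flagged
    out["threshold"] = med + adverse_sign * k * robust_sd
    return out
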
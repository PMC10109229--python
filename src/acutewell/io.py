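"""Reading, validating and cleaning the cohort tables.

The cohort is exchanged as six CSV files (UTF-8, header row, ISO-8601
timestamps with offset):

* ``profiles.csv``          — participant_id, age, gender, income_level,
  home_lat, home_lon [, true_group]
* ``daily_indicators.csv``  — participant_id, date, indicator, value
  (device streams: watch and phone daily aggregates)
* ``questionnaires.csv``    — participant_id, submitted_at, mood, stress,
  sleep_duration, sleep_quality, sport_time, encounters
* ``gps.csv``               — participant_id, timestamp, latitude, longitude
* ``sirens.csv``            — area_id, start_time
* ``heart_rate.csv``        — participant_id, timestamp, bpm

Cleaning rules: multiple questionnaire submissions on one local calendar day
collapse to the latest one; every calendar day gets a work/free label and a
study-period label.  Out-of-range values (a mood of 7, a bpm of 300) are hard
schema errors, not clamped — they indicate corruption, and silently repairing
them would bias downstream means.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .config import INDICATOR_META
from .errors import SchemaError
from .simulate import QUESTIONNAIRE_COLUMNS
from .studycal import StudyCalendar, assign_period, label_day_type

log = logging.getLogger(__name__)

_SCALE_FIELDS = ("mood", "stress", "sleep_quality")
_NONNEG_FIELDS = ("sleep_duration", "sport_time", "encounters")


@dataclass
class CohortBundle:
    """All validated cohort tables plus the calendar they are analyzed under."""

    profiles: pd.DataFrame
    daily_indicators: pd.DataFrame
    questionnaires: pd.DataFrame
    gps: pd.DataFrame
    sirens: pd.DataFrame
    heart_rate: pd.DataFrame
    calendar: StudyCalendar
    timezone: str = "Asia/Jerusalem"


def _require_columns(df: pd.DataFrame, cols, file: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing}", file=file)


def _first_bad(mask: pd.Series) -> int:
    return int(np.nonzero(mask.to_numpy())[0][0])


def _parse_timestamps(df: pd.DataFrame, col: str, file: str, tz: str) -> None:
    try:
        parsed = pd.to_datetime(df[col], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"unparseable timestamp: {exc}", file=file,
                          field=col) from None
    if parsed.isna().any():
        raise SchemaError("unparseable timestamp", file=file,
                          row=_first_bad(parsed.isna()), field=col)
    df[col] = parsed.dt.tz_convert(ZoneInfo(tz))


def _check_range(df: pd.DataFrame, col: str, lo, hi, file: str) -> None:
    bad = (df[col] < lo) | (df[col] > hi) | df[col].isna()
    if bad.any():
        row = _first_bad(bad)
        raise SchemaError(
            f"value {df[col].iloc[row]!r} outside [{lo}, {hi}]",
            file=file, row=row, field=col)


def read_profiles(path, file: str = "profiles.csv") -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "age", "gender", "income_level",
                          "home_lat", "home_lon"], file)
    _check_range(df, "age", 40, 120, file)
    _check_range(df, "home_lat", -90.0, 90.0, file)
    _check_range(df, "home_lon", -180.0, 180.0, file)
    if df["participant_id"].duplicated().any():
        raise SchemaError("duplicate participant_id",
                          file=file, row=_first_bad(df["participant_id"].duplicated()),
                          field="participant_id")
    return df


def read_daily_indicators(path, file: str = "daily_indicators.csv") -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        log.warning("%s: empty daily indicator file", file)
        return pd.DataFrame(columns=["participant_id", "date", "indicator", "value"])
    _require_columns(df, ["participant_id", "date", "indicator", "value"], file)
    unknown = ~df["indicator"].isin(INDICATOR_META)
    if unknown.any():
        row = _first_bad(unknown)
        raise SchemaError(f"unknown indicator {df['indicator'].iloc[row]!r}",
                          file=file, row=row, field="indicator")
    try:
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except ValueError as exc:
        raise SchemaError(f"unparseable date: {exc}", file=file,
                          field="date") from None
    return df


def read_questionnaires(path, tz: str = "Asia/Jerusalem",
                        file: str = "questionnaires.csv") -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        log.warning("%s: empty questionnaire file", file)
        return pd.DataFrame(columns=["participant_id", "submitted_at",
                                     *QUESTIONNAIRE_COLUMNS])
    _require_columns(df, ["participant_id", "submitted_at"], file)
    _parse_timestamps(df, "submitted_at", file, tz)
    for col in _SCALE_FIELDS:
        if col in df.columns:
            _check_range(df.dropna(subset=[col]), col, -2, 2, file)
    for col in _NONNEG_FIELDS:
        if col in df.columns:
            _check_range(df.dropna(subset=[col]), col, 0, np.inf, file)
    return df


def read_gps(path, tz: str = "Asia/Jerusalem", file: str = "gps.csv") -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        return pd.DataFrame(columns=["participant_id", "timestamp",
                                     "latitude", "longitude"])
    _require_columns(df, ["participant_id", "timestamp", "latitude",
                          "longitude"], file)
    _parse_timestamps(df, "timestamp", file, tz)
    _check_range(df, "latitude", -90.0, 90.0, file)
    _check_range(df, "longitude", -180.0, 180.0, file)
    return df


def read_sirens(path, tz: str = "Asia/Jerusalem", file: str = "sirens.csv") -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        return pd.DataFrame(columns=["area_id", "start_time"])
    _require_columns(df, ["area_id", "start_time"], file)
    _parse_timestamps(df, "start_time", file, tz)
    return df.sort_values("start_time", ignore_index=True)


def read_heart_rate(path, tz: str = "Asia/Jerusalem",
                    file: str = "heart_rate.csv") -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        return pd.DataFrame(columns=["participant_id", "timestamp", "bpm"])
    _require_columns(df, ["participant_id", "timestamp", "bpm"], file)
    _parse_timestamps(df, "timestamp", file, tz)
    bad = (df["bpm"] <= 20) | (df["bpm"] >= 250) | df["bpm"].isna()
    if bad.any():
        row = _first_bad(bad)
        raise SchemaError(f"bpm {df['bpm'].iloc[row]!r} outside physiological "
                          "bounds (20, 250)", file=file, row=row, field="bpm")
    return df


def read_cohort(in_dir, calendar: StudyCalendar | None = None,
                tz: str = "Asia/Jerusalem") -> CohortBundle:
    """Load and validate a full cohort directory."""
    d = Path(in_dir)
    calendar = calendar or StudyCalendar()
    bundle = CohortBundle(
        profiles=read_profiles(d / "profiles.csv"),
        daily_indicators=read_daily_indicators(d / "daily_indicators.csv"),
        questionnaires=read_questionnaires(d / "questionnaires.csv", tz),
        gps=read_gps(d / "gps.csv", tz),
        sirens=read_sirens(d / "sirens.csv", tz),
        heart_rate=read_heart_rate(d / "heart_rate.csv", tz),
        calendar=calendar,
        timezone=tz,
    )
    for name in ("profiles", "daily_indicators", "questionnaires", "gps",
                 "sirens", "heart_rate"):
        log.info("read_cohort: %s rows in %s", len(getattr(bundle, name)), name)
    return bundle


# ----------------------------------------------------------------- cleaning

def deduplicate_questionnaires(entries: pd.DataFrame) -> pd.DataFrame:
    """Keep the latest submission per participant and local calendar day.

    Ties on the timestamp keep the later entry in input order (logged).
    Already-unique input passes through with its rows unchanged.
    """
    if entries.empty:
        return entries
    df = entries.copy()
    day = df["submitted_at"].dt.date
    key = pd.MultiIndex.from_arrays([df["participant_id"], day])
    # stable: last occurrence wins among equal timestamps
    order = np.lexsort((np.arange(len(df)), df["submitted_at"].to_numpy()))
    ranked = df.iloc[order]
    ranked_key = key[order]
    dup_ts = (df.groupby([df["participant_id"], day])["submitted_at"]
              .nunique() != df.groupby([df["participant_id"], day]).size())
    if dup_ts.any():
        log.warning("deduplicate_questionnaires: %d participant-days have "
                    "tied timestamps; keeping later input rows",
                    int(dup_ts.sum()))
    keep = ~pd.Index(ranked_key).duplicated(keep="last")
    out = ranked[keep]
    return out.sort_values(["participant_id", "submitted_at"],
                           ignore_index=True)


def questionnaires_to_indicators(entries: pd.DataFrame) -> pd.DataFrame:
    """Melt deduplicated questionnaires into long daily-indicator rows."""
    if entries.empty:
        return pd.DataFrame(columns=["participant_id", "date", "indicator", "value"])
    df = entries.copy()
    df["date"] = pd.to_datetime(df["submitted_at"].dt.date)
    cols = [c for c in QUESTIONNAIRE_COLUMNS if c in df.columns]
    long = df.melt(id_vars=["participant_id", "date"], value_vars=cols,
                   var_name="indicator", value_name="value")
    return long.dropna(subset=["value"]).reset_index(drop=True)


def build_indicator_table(bundle: CohortBundle) -> pd.DataFrame:
    """Unified long table of all 12 indicators with day-type and period labels."""
    q = questionnaires_to_indicators(
        deduplicate_questionnaires(bundle.questionnaires))
    parts = [p for p in (bundle.daily_indicators, q) if len(p)]
    if not parts:
        return pd.DataFrame(columns=["participant_id", "date", "indicator",
                                     "value", "day_type", "period"])
    df = pd.concat(parts, ignore_index=True)
    return label_records(df, bundle.calendar)


def label_records(records: pd.DataFrame, calendar: StudyCalendar) -> pd.DataFrame:
    """Attach ``day_type`` and ``period`` columns keyed on the date."""
    df = records.copy()
    uniq = pd.Series(df["date"].unique())
    mapping = pd.DataFrame({
        "date": uniq,
        "day_type": [label_day_type(d.date(), calendar) for d in uniq],
        "period": [assign_period(d.date(), calendar) for d in uniq],
    })
    return df.merge(mapping, on="date", how="left")
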
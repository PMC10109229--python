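"""Synthetic cohort generator.

Produces a complete, self-consistent fixture set — enrollment profiles, daily
wellbeing indicators, raw questionnaires (with duplicate fills and realistic
missingness), 15-minute GPS traces, minute-level nighttime heart rate with
siren-triggered impulses, and the siren event table — whose statistical
structure matches the study design, so every downstream stage of the pipeline
can be exercised and verified without the real cohort.

Generative model for daily indicators
-------------------------------------
For participant *i* on day *t* of indicator *k*::

    y_ikt = b_ik + o_k * free(t) + w_ik * g(period(t)) + e_ikt

* ``b_ik ~ N(mu_k, sigma_between_k^2)`` — stable personal level;
* ``o_k`` — the free-day (weekend/holiday) offset producing the weekly rhythm;
* ``w_ik`` — persistent personal crisis response, drawn once per participant:
  ``w_ik ~ N(d_kg * s_k, sigma_resp_k^2)`` in exposure groups *g* with a
  nonzero configured effect size ``d_kg`` and exactly 0 elsewhere;
* ``g(period)`` is 1 during the crisis period W, ``recovery_fraction`` in
  R1/R2, and 0 at baseline;
* ``e_ikt ~ N(0, sigma_day_k^2)`` — day-to-day measurement noise.

``sigma_resp_k`` is chosen so that the SD of participant-level B->W
period-aggregate deltas equals the configured ``delta_scale`` ``s_k``:
``sigma_resp^2 = s^2 - v_agg`` where ``v_agg`` is the exact expected variance
contributed by day noise to the 5/7-2/7 weighted period means given the
calendar and fill probabilities (inclusion-conditional ``E[1/n | n >= 1]``
over binomial fill counts).  The configured ``d_kg`` is therefore the paired
Cohen's d that the full pipeline recovers, up to Monte-Carlo error.

Bounded self-report scales are clipped to [-2, 2] after noise addition, and
intrinsically nonnegative indicators are clipped at 0.
"""
from __future__ import annotations

import datetime as dt
import logging
import math
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from scipy.stats import binom

from .config import (GROUPS, INDICATOR_META, NONNEGATIVE, SCALE_BOUNDED,
                     SimulationConfig)
from .errors import ConfigurationError
from .studycal import assign_period, day_counts, label_day_type

log = logging.getLogger(__name__)

QUESTIONNAIRE_COLUMNS = ("mood", "stress", "sleep_duration", "sleep_quality",
                         "sport_time", "encounters")

# substream ids so each generator stage has an independent deterministic RNG
_STAGE = {"profiles": 1, "indicators": 2, "questionnaires": 3, "gps": 4,
          "sirens": 5, "heart_rate": 6}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], config.seed])


def _clip_values(indicator: str, values: np.ndarray) -> np.ndarray:
    if indicator in SCALE_BOUNDED:
        return np.clip(values, -2.0, 2.0)
    if indicator in NONNEGATIVE:
        return np.clip(values, 0.0, None)
    return values


# --------------------------------------------------------------------- profiles

def _destination(lat0: float, lon0: float, distance_km: float,
                 bearing_rad: float, radius_km: float = 6371.0):
    """Great-circle destination point (spherical Earth)."""
    delta = distance_km / radius_km
    phi0, lam0 = math.radians(lat0), math.radians(lon0)
    phi = math.asin(math.sin(phi0) * math.cos(delta)
                    + math.cos(phi0) * math.sin(delta) * math.cos(bearing_rad))
    lam = lam0 + math.atan2(
        math.sin(bearing_rad) * math.sin(delta) * math.cos(phi0),
        math.cos(delta) - math.sin(phi0) * math.sin(phi))
    return math.degrees(phi), math.degrees(lam)


#: hometown distance band (km) from the conflict reference point, per group
_GROUP_DISTANCE_KM = {"high": (10.0, 58.0), "medium": (62.0, 108.0),
                      "low": (115.0, 180.0)}

_AGE_BANDS = {"40-49": (40, 50), "50-59": (50, 60), "60-69": (60, 70),
              "70+": (70, 86)}


def generate_profiles(config: SimulationConfig) -> pd.DataFrame:
    """Enrollment profiles: id, demographics, hometown coordinate, true group.

    ``true_group`` is the simulation's ground-truth exposure group; the
    hometown coordinate is placed inside the matching distance band from the
    conflict reference point so geographic inference can re-derive it.
    """
    config.validate()
    rng = _rng(config, "profiles")
    n = config.n_participants

    def categorical(props: dict[str, float]) -> np.ndarray:
        keys = list(props)
        return np.array(keys)[rng.choice(len(keys), size=n, p=list(props.values()))]

    group = categorical(config.group_proportions)
    band = categorical(config.age_band_proportions)
    age = np.array([rng.integers(*_AGE_BANDS[b]) for b in band])
    gender = categorical(config.gender_proportions)
    income = categorical(config.income_proportions)

    lat0, lon0 = config.reference_point
    lats = np.empty(n)
    lons = np.empty(n)
    for i in range(n):
        lo, hi = _GROUP_DISTANCE_KM[group[i]]
        d = rng.uniform(lo, hi)
        # keep hometowns in the north-east quadrant so they stay over land-ish
        theta = rng.uniform(-0.25 * math.pi, 0.5 * math.pi)
        lats[i], lons[i] = _destination(lat0, lon0, d, theta)

    return pd.DataFrame({
        "participant_id": [f"P{i:05d}" for i in range(n)],
        "age": age.astype(int),
        "gender": gender,
        "income_level": income,
        "home_lat": lats,
        "home_lon": lons,
        "true_group": group,
    })


# ---------------------------------------------------------------- daily values

def _expected_inverse_count(n_days: int, p: float) -> float:
    """E[1/N | N >= 1] for N ~ Binomial(n_days, p); inf when p == 0."""
    if p <= 0.0:
        return math.inf
    ks = np.arange(1, n_days + 1)
    pmf = binom.pmf(ks, n_days, p)
    tail = pmf.sum()
    if tail <= 0.0:
        return math.inf
    return float((pmf / ks).sum() / tail)


def aggregation_noise_variance(config: SimulationConfig, indicator: str,
                               periods: tuple[str, str] = ("B", "W")) -> float:
    """Expected day-noise variance of the B->W weighted-period-mean delta.

    Var of one 5/7-2/7 weighted mean = day_sd^2 * ((5/7)^2 E[1/n_work | >=1]
    + (2/7)^2 E[1/n_free | >=1]); the delta adds the two period variances.
    """
    params = config.indicator_params[indicator]
    fill = config.fill_probability[INDICATOR_META[indicator]["kind"]]
    total = 0.0
    for period in periods:
        n_work, n_free = day_counts(config.calendar, period)
        total += ((5 / 7) ** 2 * _expected_inverse_count(n_work, fill)
                  + (2 / 7) ** 2 * _expected_inverse_count(n_free, fill))
    return params.day_sd ** 2 * total


def response_sd(config: SimulationConfig, indicator: str) -> float:
    """SD of the persistent crisis response, so that delta SD = delta_scale."""
    s2 = config.indicator_params[indicator].delta_scale ** 2
    v = aggregation_noise_variance(config, indicator)
    if not math.isfinite(v) or v >= s2:
        if math.isfinite(v):
            log.warning("indicator %s: day-noise variance %.4g exceeds "
                        "delta_scale^2 %.4g; crisis response is homogeneous",
                        indicator, v, s2)
        return 0.0
    return math.sqrt(s2 - v)


def _fill_masks(config: SimulationConfig, rng: np.random.Generator,
                n: int, n_days: int) -> dict[str, np.ndarray]:
    return {kind: rng.random((n, n_days)) < p
            for kind, p in config.fill_probability.items()}


def generate_daily_indicators(profiles: pd.DataFrame,
                              config: SimulationConfig) -> pd.DataFrame:
    """One row per (participant, date, indicator) that the stream recorded.

    Missingness is drawn per source stream and day: a questionnaire day
    yields all questionnaire indicators at once, a worn-watch day all watch
    indicators, etc.
    """
    if len(profiles) == 0:
        raise ConfigurationError("profiles must be non-empty")
    config.validate()
    rng = _rng(config, "indicators")
    cal = config.calendar
    dates = cal.all_dates()
    n, n_days = len(profiles), len(dates)

    is_free = np.array([label_day_type(d, cal) == "free" for d in dates])
    period = np.array([assign_period(d, cal) for d in dates])
    masks = _fill_masks(config, rng, n, n_days)
    groups = profiles["true_group"].to_numpy()
    pids = profiles["participant_id"].to_numpy()
    date_arr = np.array(dates, dtype="datetime64[D]")

    frames = []
    for ind, params in config.indicator_params.items():
        kind = INDICATOR_META[ind]["kind"]
        effects = config.war_effects.get(ind, {})
        rec = config.recovery_fraction.get(ind, 0.0)
        sigma_resp = response_sd(config, ind)

        b = params.baseline_mean + params.between_sd * rng.standard_normal(n)
        d_by_group = np.array([effects.get(g, 0.0) for g in groups])
        w = np.where(
            d_by_group != 0.0,
            d_by_group * params.delta_scale + sigma_resp * rng.standard_normal(n),
            0.0)
        gate = np.select([period == "W", np.isin(period, ("R1", "R2"))],
                         [1.0, rec], default=0.0)

        values = (b[:, None]
                  + params.free_day_offset * is_free[None, :]
                  + w[:, None] * gate[None, :]
                  + params.day_sd * rng.standard_normal((n, n_days)))
        values = _clip_values(ind, values)

        rows, cols = np.nonzero(masks[kind])
        frames.append(pd.DataFrame({
            "participant_id": pids[rows],
            "date": date_arr[cols],
            "indicator": ind,
            "value": values[rows, cols],
        }))

    out = pd.concat(frames, ignore_index=True)
    out["date"] = pd.to_datetime(out["date"])
    return out.sort_values(["participant_id", "date", "indicator"],
                           ignore_index=True)


# -------------------------------------------------------------- questionnaires

def generate_questionnaires(daily: pd.DataFrame, config: SimulationConfig
                            ) -> pd.DataFrame:
    """Raw questionnaire table derived from the self-report daily indicators.

    Each filled day becomes one submission (timestamped 08:00-23:00 local);
    with probability ``duplicate_probability`` an earlier, perturbed duplicate
    submission is prepended for the same day — downstream deduplication must
    keep the later one, which carries the true daily values.
    """
    rng = _rng(config, "questionnaires")
    tz = ZoneInfo(config.timezone)
    q = daily[daily["indicator"].isin(QUESTIONNAIRE_COLUMNS)]
    if q.empty:
        return pd.DataFrame(columns=["participant_id", "submitted_at",
                                     *QUESTIONNAIRE_COLUMNS])
    wide = (q.pivot_table(index=["participant_id", "date"], columns="indicator",
                          values="value", aggfunc="first")
            .reset_index())
    wide.columns.name = None
    present = [c for c in QUESTIONNAIRE_COLUMNS if c in wide.columns]
    m = len(wide)

    hours = rng.uniform(8.0, 23.0, size=m)
    submitted = [
        dt.datetime.combine(d.date(), dt.time()) .replace(tzinfo=tz)
        + dt.timedelta(hours=h)
        for d, h in zip(wide["date"], hours)
    ]
    rows = wide[["participant_id", *present]].copy()
    rows.insert(1, "submitted_at", submitted)

    dup_mask = rng.random(m) < config.duplicate_probability
    if dup_mask.any():
        dups = rows.loc[dup_mask].copy()
        offsets = rng.uniform(1.0, 6.0, size=len(dups))
        dups["submitted_at"] = [t - dt.timedelta(hours=o)
                                for t, o in zip(dups["submitted_at"], offsets)]
        for col in present:
            noise = rng.normal(0.0, 0.5 * config.indicator_params[col].day_sd
                               if col in config.indicator_params else 0.5,
                               size=len(dups))
            dups[col] = _clip_values(col, dups[col].to_numpy() + noise)
        rows = pd.concat([rows, dups], ignore_index=True)

    return rows.sort_values(["participant_id", "submitted_at"],
                            ignore_index=True)


# ------------------------------------------------------------------ GPS traces

def generate_gps_traces(profiles: pd.DataFrame, config: SimulationConfig
                        ) -> pd.DataFrame:
    """15-minute GPS samples; nights concentrate at the hometown coordinate.

    A configurable fraction of nights is spent away from home (at a random
    offset location), and a configurable fraction of participants produces no
    GPS at all, exercising the hometown fallback of residence inference.
    """
    config.validate()
    rng = _rng(config, "gps")
    g = config.gps
    tz = ZoneInfo(config.timezone)
    cal = config.calendar
    dates = cal.all_dates()

    minutes = np.arange(0, 24 * 60, g.interval_minutes)
    if g.clock_window is not None:
        lo, hi = g.clock_window
        minutes = minutes[(minutes >= lo * 60) & (minutes < hi * 60)]
    hour_of_day = minutes / 60.0
    night = (hour_of_day >= g.night_start_hour) & (hour_of_day < g.night_end_hour)

    no_gps = rng.random(len(profiles)) < g.no_gps_fraction
    frames = []
    base = pd.DatetimeIndex([dt.datetime.combine(d, dt.time(), tzinfo=tz)
                             for d in dates])
    for i, row in enumerate(profiles.itertuples(index=False)):
        if no_gps[i]:
            continue
        away = rng.random(len(dates)) < g.away_fraction
        away_pts = np.column_stack([
            row.home_lat + rng.normal(0, 0.5, len(dates)),
            row.home_lon + rng.normal(0, 0.5, len(dates))])
        n_pts = len(dates) * len(minutes)
        lat = np.full(n_pts, row.home_lat)
        lon = np.full(n_pts, row.home_lon)
        night_full = np.tile(night, len(dates))
        away_full = np.repeat(away, len(minutes))
        day_sel = ~night_full
        lat[day_sel] += rng.normal(0, g.day_jitter_deg, day_sel.sum())
        lon[day_sel] += rng.normal(0, g.day_jitter_deg, day_sel.sum())
        away_sel = night_full & away_full
        lat[away_sel] = np.repeat(away_pts[:, 0], len(minutes))[away_sel]
        lon[away_sel] = np.repeat(away_pts[:, 1], len(minutes))[away_sel]
        home_sel = night_full & ~away_full
        if g.jitter_deg > 0:
            lat[home_sel] += rng.normal(0, g.jitter_deg, home_sel.sum())
            lon[home_sel] += rng.normal(0, g.jitter_deg, home_sel.sum())
            lat[away_sel] += rng.normal(0, g.jitter_deg, away_sel.sum())
            lon[away_sel] += rng.normal(0, g.jitter_deg, away_sel.sum())
        ts = (base.repeat(len(minutes))
              + pd.TimedeltaIndex(np.tile(pd.to_timedelta(minutes, unit="m"),
                                          len(dates))))
        frames.append(pd.DataFrame({
            "participant_id": row.participant_id,
            "timestamp": ts, "latitude": lat, "longitude": lon}))

    if not frames:
        return pd.DataFrame(columns=["participant_id", "timestamp",
                                     "latitude", "longitude"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------- sirens

def generate_sirens(config: SimulationConfig) -> pd.DataFrame:
    """Siren events per night and area during the crisis period.

    Counts are Poisson per (night, area); times are uniform inside the
    configured night window, rounded to the minute.
    """
    rng = _rng(config, "sirens")
    tz = ZoneInfo(config.timezone)
    lo, hi = config.sirens.night_window
    rows = []
    for date in config.calendar.dates_in("W"):
        midnight = dt.datetime.combine(date, dt.time(), tzinfo=tz)
        for area in GROUPS:
            rate = config.sirens.events_per_night.get(area, 0.0)
            if rate <= 0:
                continue
            for _ in range(rng.poisson(rate)):
                minute = int(rng.uniform(lo * 60, hi * 60))
                rows.append((area, midnight + dt.timedelta(minutes=minute)))
    df = pd.DataFrame(rows, columns=["area_id", "start_time"])
    return df.sort_values(["start_time", "area_id"], ignore_index=True)


# ------------------------------------------------------------------ heart rate

def generate_hr_series(profiles: pd.DataFrame, sirens: pd.DataFrame,
                       config: SimulationConfig) -> pd.DataFrame:
    """Minute-level heart rate with additive exponentially-decaying siren impulses.

    bpm(t) = personal baseline + diurnal cosine (trough ~04:00) + white noise
    + sum over sirens in the participant's area of amp * exp(-dt / tau) for
    dt >= 0.  Impulse amplitude is drawn per participant-event.  Samples are
    emitted inside the configured clock window, by default only on crisis-period
    dates (the nighttime siren analysis needs nothing else).
    """
    config.validate()
    rng = _rng(config, "heart_rate")
    hr = config.heart_rate
    tz = ZoneInfo(config.timezone)
    cal = config.calendar
    dates = cal.dates_in("W") if hr.war_period_only else cal.all_dates()
    start, end = cal.start, cal.end

    lo, hi = hr.clock_window
    minutes = np.arange(int(lo * 60), int(hi * 60))
    grid = []
    for d in dates:
        midnight = dt.datetime.combine(d, dt.time(), tzinfo=tz)
        grid.append(pd.Timestamp(midnight).value // 60_000_000_000 + minutes)
    epoch_min = np.concatenate(grid)          # absolute minutes since epoch
    ts = pd.to_datetime(epoch_min * 60_000_000_000).tz_localize("UTC").tz_convert(tz)
    hour = np.tile(minutes / 60.0, len(dates))
    diurnal = hr.diurnal_amplitude_bpm * np.cos(2 * np.pi * (hour - 16.0) / 24.0)

    sirens_by_area: dict[str, list[int]] = {}
    for ev in sirens.itertuples(index=False):
        t = pd.Timestamp(ev.start_time)
        if not (start <= t.date() <= end):
            log.warning("siren at %s outside the simulated date range; skipped", t)
            continue
        sirens_by_area.setdefault(ev.area_id, []).append(
            t.value // 60_000_000_000)

    tau = config.sirens.decay_minutes
    frames = []
    for row in profiles.itertuples(index=False):
        base = (hr.baseline_mean_bpm
                + hr.baseline_sd_bpm * rng.standard_normal())
        bpm = base + diurnal + hr.noise_sd_bpm * rng.standard_normal(len(epoch_min))
        for s_min in sirens_by_area.get(row.true_group, ()):
            amp = max(0.0, rng.normal(config.sirens.amplitude_mean_bpm,
                                      config.sirens.amplitude_sd_bpm))
            dtm = epoch_min - s_min
            sel = (dtm >= 0) & (dtm <= 12 * tau)
            bpm[sel] += amp * np.exp(-dtm[sel] / tau)
        frames.append(pd.DataFrame({
            "participant_id": row.participant_id,
            "timestamp": ts, "bpm": bpm}))
    if not frames:
        return pd.DataFrame(columns=["participant_id", "timestamp", "bpm"])
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------------- full set

def generate_cohort(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Generate every fixture table; deterministic given (config, seed)."""
    profiles = generate_profiles(config)
    daily = generate_daily_indicators(profiles, config)
    questionnaires = generate_questionnaires(daily, config)
    gps = generate_gps_traces(profiles, config)
    sirens = generate_sirens(config)
    heart_rate = generate_hr_series(profiles, sirens, config)
    device = daily[~daily["indicator"].isin(QUESTIONNAIRE_COLUMNS)]
    return {
        "profiles": profiles,
        "daily_indicators": device.reset_index(drop=True),
        "questionnaires": questionnaires,
        "gps": gps,
        "sirens": sirens,
        "heart_rate": heart_rate,
        "_truth_daily": daily,   # all 12 streams, pre-split (not written out)
    }


def write_cohort(tables: dict[str, pd.DataFrame], out_dir,
                 config: SimulationConfig | None = None) -> None:
    """Write the fixture CSVs (ISO-8601 timestamps) and the driving config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def iso(series: pd.Series) -> pd.Series:
        return series.map(lambda t: pd.Timestamp(t).isoformat())

    tables["profiles"].to_csv(out / "profiles.csv", index=False)
    daily = tables["daily_indicators"].copy()
    daily["date"] = daily["date"].dt.strftime("%Y-%m-%d")
    daily.to_csv(out / "daily_indicators.csv", index=False)
    q = tables["questionnaires"].copy()
    if len(q):
        q["submitted_at"] = iso(q["submitted_at"])
    q.to_csv(out / "questionnaires.csv", index=False)
    gps = tables["gps"].copy()
    if len(gps):
        gps["timestamp"] = iso(gps["timestamp"])
    gps.to_csv(out / "gps.csv", index=False)
    sirens = tables["sirens"].copy()
    if len(sirens):
        sirens["start_time"] = iso(sirens["start_time"])
    sirens.to_csv(out / "sirens.csv", index=False)
    hr = tables["heart_rate"].copy()
    if len(hr):
        hr["timestamp"] = iso(hr["timestamp"])
    hr.to_csv(out / "heart_rate.csv", index=False)
    if config is not None:
        config.to_yaml(out / "config.yaml")
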
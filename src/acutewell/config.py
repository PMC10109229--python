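"""Simulation configuration: study-design constants and generator knobs.

The defaults encode the study conditions: a 954-person cohort of adults aged
40+, demographic and exposure-group composition matching the published cohort
table, four contiguous periods around the May 2021 crisis, ~2-3 questionnaire
fills per week, and crisis-period shifts sized in Cohen's d per exposure
group.

Effect sizing
-------------
``war_effects[indicator][group]`` is the standardized shift (Cohen's d) that
the full pipeline should recover as the *paired* Cohen's d of the
participant-level B->W period-aggregate deltas.  Each indicator therefore
carries a ``delta_scale`` — the target SD of those deltas — and the generator
splits it into a persistent per-participant crisis response plus day-level
measurement noise (see :mod:`acutewell.simulate`).  Default ``delta_scale``
values are derived from the published mean-change / effect-size ratios;
baseline means and SDs are plausible placeholders (the study's per-indicator
baseline table is not reproduced here).
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .errors import ConfigurationError
from .studycal import StudyCalendar, DEFAULT_PERIOD_RANGES

GROUPS = ("high", "medium", "low")

#: Canonical indicator names, their source stream and measurement units.
#: ``adverse`` is the sign of a change for the worse (used by the
#: non-recovery flagging rule).
INDICATOR_META: dict[str, dict[str, Any]] = {
    "screen_on_time":  {"kind": "phone",         "units": "hour",    "adverse": +1},
    "mood":            {"kind": "questionnaire", "units": "scale",   "adverse": -1},
    "stress":          {"kind": "questionnaire", "units": "scale",   "adverse": +1},
    "encounters":      {"kind": "questionnaire", "units": "count",   "adverse": -1},
    "steps":           {"kind": "watch",         "units": "count",   "adverse": -1},
    "heart_rate":      {"kind": "watch",         "units": "bpm",     "adverse": -1},
    "pct_time_still":  {"kind": "phone",         "units": "percent", "adverse": +1},
    "sport_time":      {"kind": "questionnaire", "units": "minute",  "adverse": -1},
    "awake_time":      {"kind": "watch",         "units": "second",  "adverse": +1},
    "sleep_start":     {"kind": "watch",         "units": "hour",    "adverse": +1},
    "sleep_duration":  {"kind": "questionnaire", "units": "hour",    "adverse": -1},
    "sleep_quality":   {"kind": "questionnaire", "units": "scale",   "adverse": -1},
}

INDICATORS = tuple(INDICATOR_META)

#: Self-report scales are bounded to -2..2.
SCALE_BOUNDED = {"mood", "stress", "sleep_quality"}
#: Indicators that cannot go negative.
NONNEGATIVE = {"screen_on_time", "encounters", "steps", "pct_time_still",
               "sport_time", "awake_time", "sleep_duration"}


@dataclass
class IndicatorParams:
    """Generator parameters for one daily wellbeing indicator.

    ``delta_scale`` is the target SD of participant-level B->W period-aggregate
    deltas, i.e. the denominator of the paired Cohen's d the pipeline recovers.
    """

    baseline_mean: float
    between_sd: float
    day_sd: float
    free_day_offset: float
    delta_scale: float


# (baseline_mean, between_sd, day_sd, free_day_offset, delta_scale)
_DEFAULT_INDICATOR_PARAMS: dict[str, tuple[float, float, float, float, float]] = {
    "screen_on_time":  (4.0,    1.5,   1.5,   +0.4,   2.298),
    "mood":            (0.5,    0.6,   0.6,   +0.15,  0.635),
    "stress":          (-0.2,   0.6,   0.6,   -0.10,  0.654),
    "encounters":      (8.0,    4.0,   5.0,   +2.0,  10.25),
    "steps":           (7000.0, 2500.0, 2500.0, -500.0, 3878.0),
    "heart_rate":      (68.0,   7.0,   2.5,   -0.5,   8.09),
    "pct_time_still":  (60.0,  10.0,   6.0,   +3.0,   7.0),
    "sport_time":      (30.0,  20.0,  25.0,  +10.0,  33.4),
    "awake_time":      (1800.0, 600.0, 500.0, +100.0, 684.0),
    "sleep_start":     (-0.5,   1.0,   0.75,  +0.5,   1.62),
    "sleep_duration":  (7.0,    0.8,   0.9,   +0.5,   0.906),
    "sleep_quality":   (0.5,    0.6,   0.6,   +0.1,   0.643),
}

#: Default crisis-period standardized shifts per exposure group.  Where the
#: study reports per-group effect sizes (six indicators with significant
#: period x group interactions) those are used for high/medium; elsewhere the
#: population effect size is applied to both affected groups; the low group
#: is unaffected except for screen-on time.
_DEFAULT_WAR_EFFECTS: dict[str, dict[str, float]] = {
    "screen_on_time": {"high": +0.48, "medium": +0.28, "low": +0.17},
    "mood":           {"high": -1.21, "medium": -0.51, "low": 0.0},
    "stress":         {"high": +1.33, "medium": +0.50, "low": 0.0},
    "encounters":     {"high": -0.16, "medium": -0.16, "low": 0.0},
    "steps":          {"high": -0.19, "medium": -0.19, "low": 0.0},
    "heart_rate":     {"high": -0.11, "medium": -0.11, "low": 0.0},
    "pct_time_still": {"high": +0.20, "medium": +0.20, "low": 0.0},
    "sport_time":     {"high": -0.48, "medium": -0.22, "low": 0.0},
    "awake_time":     {"high": +0.32, "medium": +0.32, "low": 0.0},
    "sleep_start":    {"high": +0.09, "medium": +0.09, "low": 0.0},
    "sleep_duration": {"high": -0.42, "medium": -0.20, "low": 0.0},
    "sleep_quality":  {"high": -1.23, "medium": -0.24, "low": 0.0},
}


@dataclass
class GpsParams:
    """GPS trace generator parameters (degrees / minutes / fractions)."""

    interval_minutes: int = 15
    jitter_deg: float = 0.0005          # night-sample scatter around home
    day_jitter_deg: float = 0.01        # daytime movement scatter
    away_fraction: float = 0.05         # fraction of nights spent away from home
    no_gps_fraction: float = 0.05       # participants with no GPS at all
    night_start_hour: float = 0.0       # "night" for away/home logic
    night_end_hour: float = 7.0
    clock_window: tuple[float, float] | None = None  # restrict emitted samples


@dataclass
class SirenParams:
    """Siren schedule and heart-rate impulse parameters."""

    events_per_night: dict[str, float] = field(
        default_factory=lambda: {"high": 3.0, "medium": 1.0, "low": 0.0})
    night_window: tuple[float, float] = (0.0, 7.0)   # clock hours for events
    amplitude_mean_bpm: float = 16.0
    amplitude_sd_bpm: float = 5.0
    decay_minutes: float = 6.0


@dataclass
class HeartRateParams:
    """Minute-level heart-rate stream parameters."""

    baseline_mean_bpm: float = 62.0
    baseline_sd_bpm: float = 7.0
    noise_sd_bpm: float = 2.0
    diurnal_amplitude_bpm: float = 3.0   # peak-to-mean of the 24h cycle
    clock_window: tuple[float, float] = (0.0, 7.0)
    war_period_only: bool = True


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort."""

    n_participants: int = 954
    seed: int = 0
    timezone: str = "Asia/Jerusalem"
    calendar: StudyCalendar = field(default_factory=StudyCalendar)
    group_proportions: dict[str, float] = field(
        default_factory=lambda: {"high": 68 / 954, "medium": 704 / 954,
                                 "low": 182 / 954})
    age_band_proportions: dict[str, float] = field(
        default_factory=lambda: {"40-49": 89 / 954, "50-59": 407 / 954,
                                 "60-69": 311 / 954, "70+": 147 / 954})
    gender_proportions: dict[str, float] = field(
        default_factory=lambda: {"man": 405 / 954, "woman": 549 / 954})
    income_proportions: dict[str, float] = field(
        default_factory=lambda: {"above_median": 475 / 954, "median": 185 / 954,
                                 "below_median": 258 / 954,
                                 "unspecified": 36 / 954})
    indicator_params: dict[str, IndicatorParams] = field(
        default_factory=lambda: {k: IndicatorParams(*v)
                                 for k, v in _DEFAULT_INDICATOR_PARAMS.items()})
    war_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in _DEFAULT_WAR_EFFECTS.items()})
    #: fraction of the crisis shift persisting into R1/R2 (0 = full recovery)
    recovery_fraction: dict[str, float] = field(
        default_factory=lambda: {k: 0.0 for k in INDICATORS})
    #: daily fill probability per source stream
    fill_probability: dict[str, float] = field(
        default_factory=lambda: {"questionnaire": 2.5 / 7, "watch": 0.9,
                                 "phone": 0.8})
    duplicate_probability: float = 0.05  # chance a filled day gets a stale duplicate
    gps: GpsParams = field(default_factory=GpsParams)
    sirens: SirenParams = field(default_factory=SirenParams)
    heart_rate: HeartRateParams = field(default_factory=HeartRateParams)
    #: conflict reference coordinate (lat, lon) used to place hometowns
    reference_point: tuple[float, float] = (31.5017, 34.4668)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        for name, props in [
            ("group_proportions", self.group_proportions),
            ("age_band_proportions", self.age_band_proportions),
            ("gender_proportions", self.gender_proportions),
            ("income_proportions", self.income_proportions),
        ]:
            total = sum(props.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigurationError(
                    f"{name} must sum to 1 (got {total!r})")
            if any(v < 0 for v in props.values()):
                raise ConfigurationError(f"{name} contains a negative value")
        if set(self.group_proportions) != set(GROUPS):
            raise ConfigurationError(
                f"group_proportions keys must be {set(GROUPS)}")
        for ind in self.indicator_params:
            if ind not in INDICATOR_META:
                raise ConfigurationError(
                    f"indicator_params: unknown indicator {ind!r}")
        for ind, p in self.indicator_params.items():
            for fld in ("between_sd", "day_sd", "delta_scale"):
                if getattr(p, fld) < 0:
                    raise ConfigurationError(
                        f"indicator_params[{ind}].{fld} must be nonnegative")
        for ind, effects in self.war_effects.items():
            if ind not in INDICATOR_META:
                raise ConfigurationError(
                    f"war_effects: unknown indicator {ind!r}")
            for g in effects:
                if g not in GROUPS:
                    raise ConfigurationError(
                        f"war_effects[{ind}]: unknown group {g!r}")
        for stream, p in self.fill_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"fill_probability[{stream}] must be in [0, 1]")
        for fld, val in [("duplicate_probability", self.duplicate_probability),
                         ("gps.away_fraction", self.gps.away_fraction),
                         ("gps.no_gps_fraction", self.gps.no_gps_fraction)]:
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{fld} must be in [0, 1]")
        if self.gps.jitter_deg < 0 or self.gps.day_jitter_deg < 0:
            raise ConfigurationError("gps jitter must be nonnegative")
        if self.sirens.decay_minutes <= 0:
            raise ConfigurationError("sirens.decay_minutes must be positive")
        if self.heart_rate.noise_sd_bpm < 0:
            raise ConfigurationError("heart_rate.noise_sd_bpm must be nonnegative")

    # ---------------------------------------------------------------- YAML IO
    def to_dict(self) -> dict[str, Any]:
        def listify(x):
            if isinstance(x, (tuple, list)):
                return [listify(v) for v in x]
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            return x

        d = listify(asdict(self))
        cal = self.calendar
        d["calendar"] = {
            "period_ranges": {p: [str(r[0]), str(r[1])]
                              for p, r in cal.period_ranges.items()},
            "weekend_days": sorted(cal.weekend_days),
            "holidays": sorted(str(h) for h in cal.holidays),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "calendar" in d and not isinstance(d["calendar"], StudyCalendar):
            c = d["calendar"]
            d["calendar"] = StudyCalendar(
                period_ranges={p: (dt.date.fromisoformat(a),
                                   dt.date.fromisoformat(b))
                               for p, (a, b) in c.get(
                                   "period_ranges",
                                   {p: [str(r[0]), str(r[1])]
                                    for p, r in DEFAULT_PERIOD_RANGES.items()}
                               ).items()},
                weekend_days=frozenset(c.get("weekend_days", (4, 5))),
                holidays=frozenset(dt.date.fromisoformat(h)
                                   for h in c.get("holidays", ())),
            )
        if "indicator_params" in d:
            d["indicator_params"] = {
                k: v if isinstance(v, IndicatorParams) else IndicatorParams(**v)
                for k, v in d["indicator_params"].items()}
        for key, klass in [("gps", GpsParams), ("sirens", SirenParams),
                           ("heart_rate", HeartRateParams)]:
            if key in d and not isinstance(d[key], klass):
                sub = dict(d[key])
                for tup in ("clock_window", "night_window"):
                    if sub.get(tup) is not None and tup in sub:
                        sub[tup] = tuple(sub[tup])
                d[key] = klass(**sub)
        if "reference_point" in d:
            d["reference_point"] = tuple(d["reference_point"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def single_indicator_config(indicator: str, **overrides) -> SimulationConfig:
    """A config restricted to one indicator — convenient for focused simulations."""
    cfg = SimulationConfig(**overrides)
    cfg.indicator_params = {indicator: cfg.indicator_params[indicator]}
    cfg.war_effects = {indicator: cfg.war_effects[indicator]}
    cfg.recovery_fraction = {indicator: cfg.recovery_fraction[indicator]}
    return cfg
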
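"""Study calendar: the four analysis periods and the work/free day labelling.

The analysis window is split into four contiguous periods:

* ``B``  — baseline, the two weeks before the crisis;
* ``W``  — the crisis (war) period itself;
* ``R1`` — first back-to-routine fortnight;
* ``R2`` — second back-to-routine fortnight.

Days are further labelled ``work`` or ``free``; free days are weekend days
(Friday-Saturday by default, the Israeli weekend) and national holidays.
The free/work distinction drives the 5/7-2/7 weighted period mean in
:mod:`acutewell.aggregate`.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .errors import ConfigurationError

PERIODS = ("B", "W", "R1", "R2")

#: Default period boundaries (closed ranges), May 2021 crisis.
DEFAULT_PERIOD_RANGES: dict[str, tuple[dt.date, dt.date]] = {
    "B": (dt.date(2021, 4, 26), dt.date(2021, 5, 9)),
    "W": (dt.date(2021, 5, 10), dt.date(2021, 5, 20)),
    "R1": (dt.date(2021, 5, 21), dt.date(2021, 6, 3)),
    "R2": (dt.date(2021, 6, 4), dt.date(2021, 6, 17)),
}

#: Friday=4, Saturday=5 (datetime.weekday convention).
DEFAULT_WEEKEND_DAYS = frozenset({4, 5})

#: Shavuot fell inside the default war period.
DEFAULT_HOLIDAYS = frozenset({dt.date(2021, 5, 17)})


@dataclass(frozen=True)
class StudyCalendar:
    """Period ranges plus the weekend/holiday definition of a free day."""

    period_ranges: dict[str, tuple[dt.date, dt.date]] = field(
        default_factory=lambda: dict(DEFAULT_PERIOD_RANGES))
    weekend_days: frozenset[int] = DEFAULT_WEEKEND_DAYS
    holidays: frozenset[dt.date] = DEFAULT_HOLIDAYS

    def __post_init__(self) -> None:
        missing = [p for p in PERIODS if p not in self.period_ranges]
        if missing:
            raise ConfigurationError(f"period_ranges missing periods: {missing}")
        prev_end = None
        for p in PERIODS:
            start, end = self.period_ranges[p]
            if start > end:
                raise ConfigurationError(
                    f"period_ranges[{p}]: start {start} after end {end}")
            if prev_end is not None and start <= prev_end:
                raise ConfigurationError(
                    f"period_ranges[{p}] overlaps or precedes the previous period")
            prev_end = end
        if not all(0 <= d <= 6 for d in self.weekend_days):
            raise ConfigurationError("weekend_days must be weekday indices 0-6")

    @property
    def start(self) -> dt.date:
        return self.period_ranges["B"][0]

    @property
    def end(self) -> dt.date:
        return self.period_ranges["R2"][1]

    def all_dates(self) -> list[dt.date]:
        """Every calendar day in B..R2 (inclusive)."""
        n = (self.end - self.start).days + 1
        return [self.start + dt.timedelta(days=i) for i in range(n)]

    def dates_in(self, period: str) -> list[dt.date]:
        start, end = self.period_ranges[period]
        n = (end - start).days + 1
        return [start + dt.timedelta(days=i) for i in range(n)]


def label_day_type(date: dt.date, calendar: StudyCalendar) -> str:
    """``free`` iff the date is a weekend day or a national holiday, else ``work``."""
    if date.weekday() in calendar.weekend_days or date in calendar.holidays:
        return "free"
    return "work"


def assign_period(date: dt.date, calendar: StudyCalendar) -> str:
    """Period label of a date by closed-range membership; ``none`` outside all four."""
    for p in PERIODS:
        start, end = calendar.period_ranges[p]
        if start <= date <= end:
            return p
    return "none"


def day_counts(calendar: StudyCalendar, period: str) -> tuple[int, int]:
    """(work, free) day counts inside one period."""
    days = calendar.dates_in(period)
    free = sum(1 for d in days if label_day_type(d, calendar) == "free")
    return len(days) - free, free
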
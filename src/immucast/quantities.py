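"""Durations with explicit units and whole-unit calendar arithmetic.

Schedule thresholds are stored in the unit the source states them in (days,
weeks, calendar months, years) and are never pre-converted to days at rest:
"12 months" means the 12-month *calendar anniversary* (clamped to month end),
which is not a fixed number of days.  Comparisons against an age or interval
are made at the granularity of the stated unit, so ">= 12 mo" is true on the
anniversary day and "> 12 mo" becomes true only once 13 whole months have
elapsed.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, timedelta
from enum import Enum

from dateutil.relativedelta import relativedelta


class Unit(str, Enum):
    DAYS = "d"
    WEEKS = "wk"
    MONTHS = "mo"
    YEARS = "y"
    DOSES = "doses"  # dose-count thresholds carry this unit


_DURATION_RE = re.compile(r"^\s*(\d+)\s*(d|wk|mo|y|doses)\s*$")


@dataclass(frozen=True)
class Duration:
    """A non-negative amount of calendar time (or a dose count)."""

    value: int
    unit: Unit

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("duration value must be non-negative")

    def __str__(self) -> str:
        return f"{self.value} {self.unit.value}"

    @classmethod
    def parse(cls, text: str) -> "Duration":
        m = _DURATION_RE.match(text)
        if not m:
            raise ValueError(f"cannot parse duration {text!r}")
        return cls(int(m.group(1)), Unit(m.group(2)))


def add_duration(start: date, dur: Duration) -> date:
    """Shift ``start`` forward by ``dur``.

    Month/year shifts land on the same day-of-month anniversary, clamped to
    the end of the target month (Jan 31 + 1 mo -> Feb 28/29).
    """
    if dur.unit is Unit.DAYS:
        return start + timedelta(days=dur.value)
    if dur.unit is Unit.WEEKS:
        return start + timedelta(days=7 * dur.value)
    if dur.unit is Unit.MONTHS:
        return start + relativedelta(months=dur.value)
    if dur.unit is Unit.YEARS:
        return start + relativedelta(months=12 * dur.value)
    raise ValueError(f"cannot add {dur.unit} to a date")


def whole_months_between(start: date, end: date) -> int:
    """Largest m with start + m clamped calendar months <= end."""
    if end < start:
        raise ValueError("end precedes start")
    m = (end.year - start.year) * 12 + (end.month - start.month)
    if add_duration(start, Duration(m, Unit.MONTHS)) > end:
        m -= 1
    return m


def whole_elapsed(start: date, end: date, unit: Unit) -> int:
    """Whole units of ``unit`` elapsed from ``start`` to ``end`` (floor)."""
    if end < start:
        raise ValueError("end precedes start")
    if unit is Unit.DAYS:
        return (end - start).days
    if unit is Unit.WEEKS:
        return (end - start).days // 7
    if unit is Unit.MONTHS:
        return whole_months_between(start, end)
    if unit is Unit.YEARS:
        return whole_months_between(start, end) // 12
    raise ValueError(f"{unit} is not a calendar unit")
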
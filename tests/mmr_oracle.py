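"""Independently hand-coded MMR decision table, used as an oracle.

Deliberately shares no code with the engine: month arithmetic is a naive
calendar walk over (year, month, day) tuples, and the schedule logic is a
flat if/else table (12-month minimum age, 28-day minimum interval, 4-day
grace, dose 2 routine at 4-6 years, 2-dose series).
"""
from __future__ import annotations

import calendar
from datetime import date, timedelta
from typing import List, Optional, Tuple

GRACE_DAYS = 4
MIN_INTERVAL_DAYS = 28


def add_months(d: date, n: int) -> date:
    """Same-day-of-month anniversary, clamped to month end."""
    month_index = d.year * 12 + (d.month - 1) + n
    year, month = divmod(month_index, 12)
    month += 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return date(year, month, day)


def whole_months(birth: date, as_of: date) -> int:
    m = 0
    while add_months(birth, m + 1) <= as_of:
        m += 1
    return m


def valid_dose_dates(birth: date, dose_dates: List[date]) -> List[date]:
    valid: List[date] = []
    for d in sorted(dose_dates):
        if len(valid) >= 2:
            break
        if d < add_months(birth, 12) - timedelta(days=GRACE_DAYS):
            continue
        if valid and d < valid[-1] + timedelta(days=MIN_INTERVAL_DAYS - GRACE_DAYS):
            continue
        valid.append(d)
    return valid


def expected_mmr(birth: date, dose_dates: List[date], contraindicated: bool,
                 as_of: date) -> Tuple[str, Optional[int]]:
    """(action, dose_number) the schedule demands for a clean, complete record."""
    if contraindicated:
        return "CONTRAINDICATED", None
    valid = valid_dose_dates(birth, dose_dates)
    if len(valid) >= 2:
        return "SERIES_COMPLETE", None
    months = whole_months(birth, as_of)
    if not valid:
        if months < 12:
            return "SCHEDULE_FOLLOWUP", 1
        return "RECOMMEND_DOSE", 1
    # exactly one valid dose
    if months < 48:
        return "SCHEDULE_FOLLOWUP", 2
    first_administered = min(dose_dates)
    if (as_of - first_administered).days >= MIN_INTERVAL_DAYS:
        return "RECOMMEND_DOSE", 2
    return "SCHEDULE_FOLLOWUP", 2


def patient_grid(as_of: date):
    """Synthetic MMR grid: monthly ages 0-18 y x dose histories x
    contraindication on/off.  Yields (birth, dose_dates, contra, expected)."""
    for age_months in range(0, 217):
        birth = add_months(as_of, -age_months)
        d1 = add_months(birth, 12) + timedelta(days=10)   # valid dose 1
        early = add_months(birth, 11)                      # invalid: too young
        late1 = add_months(birth, 16) + timedelta(days=3)  # late but valid
        d2 = add_months(birth, 48) + timedelta(days=10)    # valid dose 2
        short2 = d1 + timedelta(days=20)                   # invalid interval
        histories: List[List[date]] = [[]]
        if d1 <= as_of:
            histories.append([d1])
        if early <= as_of:
            histories.append([early])
        if late1 <= as_of:
            histories.append([late1])
        if d2 <= as_of:
            histories.append([d1, d2])
        if short2 <= as_of:
            histories.append([d1, short2])
        for doses in histories:
            for contra in (False, True):
                yield birth, doses, contra, expected_mmr(birth, doses, contra, as_of)
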
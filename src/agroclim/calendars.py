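"""Month-day windows and southern-hemisphere season-year conventions.

A *season year* (harvest year) labels the July–June agronomic year ending on
30 June of that calendar year, the natural growing-season bracket for
southern-hemisphere cropping.  Sensitive-period windows are given as
``"MM-DD"`` month-day pairs; a window whose end month-day precedes its start
(e.g. 15 Dec – 15 Feb) spans the calendar-year boundary and belongs to the
season year of its *end* date.
"""

from __future__ import annotations

import calendar
import datetime as _dt

import pandas as pd

from .errors import InputError

#: Month-day on which a season year ends (30 June of the label year).
SEASON_END_MONTH_DAY = (6, 30)


def parse_month_day(text: str) -> tuple[int, int]:
    """Parse an ``"MM-DD"`` string into a validated (month, day) pair."""
    try:
        month_s, day_s = text.split("-")
        month, day = int(month_s), int(day_s)
    except (ValueError, AttributeError) as exc:
        raise InputError(f"cannot parse month-day {text!r}; expected 'MM-DD'") from exc
    if not 1 <= month <= 12:
        raise InputError(f"month out of range in {text!r}")
    # Validate the day against the longest variant of the month (leap Feb).
    if not 1 <= day <= calendar.monthrange(2000, month)[1]:
        raise InputError(f"day out of range in {text!r}")
    return month, day


def resolve_date(year: int, month_day: tuple[int, int]) -> pd.Timestamp:
    """Concrete date for a month-day in a given year; 29 Feb falls back to
    28 Feb in non-leap years."""
    month, day = month_day
    if month == 2 and day == 29 and not calendar.isleap(year):
        day = 28
    return pd.Timestamp(_dt.date(year, month, day))


def resolve_window(
    season_year: int, start: tuple[int, int], end: tuple[int, int]
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Concrete (start, end) dates of a month-day window for a season year.

    Windows with end >= start lie inside the calendar year equal to the
    season label; cross-boundary windows start in the preceding year.
    """
    if start == end:
        raise InputError("window start and end month-days must differ")
    start_year = season_year if start <= end else season_year - 1
    return resolve_date(start_year, start), resolve_date(season_year, end)


def season_bounds(season_year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """1 July (preceding year) to 30 June of the season year, inclusive."""
    return (
        pd.Timestamp(season_year - 1, 7, 1),
        pd.Timestamp(season_year, *SEASON_END_MONTH_DAY),
    )


def season_month_index(month: int) -> int:
    """Order months within a July-June season: Jul -> 0 ... Jun -> 11."""
    return (month - 7) % 12
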
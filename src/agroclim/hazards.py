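"""Threshold-exceedance crop hazards over date-windowed sensitive periods.

The simplest tier of risk model: for each crop a hazard is a strict
threshold on one daily variable (heat stress on tmax, frost on tmin) or a
sliding-window extreme-rainfall rule, evaluated only inside a month-day
sensitive window.  Risk change between climates is the difference of mean
annual event-day counts per cell.

The built-in specification table covers the eleven crop x hazard rules for
six arable crops (chestnuts, onions, peas, potatoes, wheat, maize grown in
a New Zealand-like southern-hemisphere calendar).  Comparators are strict
(``>`` / ``<``) for thresholds; the rainfall rule's per-day qualifier is
inclusive (``>=``), matching how such rules are conventionally stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .calendars import parse_month_day, resolve_window
from .climate import DailyClimateSeries
from .errors import AlignmentError, CoverageError, InputError

HazardKind = Literal["heat_stress", "frost", "extreme_rainfall"]


@dataclass(frozen=True)
class RainRule:
    """k days within any m-day span receiving at least ``min_daily_mm``."""

    k_days: int
    span_days: int
    min_daily_mm: float

    def __post_init__(self) -> None:
        if not 1 <= self.k_days <= self.span_days:
            raise InputError("rain rule needs 1 <= k_days <= span_days")
        if self.min_daily_mm < 0:
            raise InputError("rain rule daily amount must be >= 0")


@dataclass(frozen=True)
class HazardSpec:
    """One crop x hazard rule: variable, strict comparator, critical value
    and the month-day sensitive window it applies in."""

    crop_name: str
    hazard_kind: HazardKind
    variable: Literal["tmax", "tmin", "precip"]
    comparator: Literal[">", "<"]
    critical_value: float
    window_start: str  # "MM-DD"
    window_end: str  # "MM-DD"
    rain_rule: RainRule | None = None

    def __post_init__(self) -> None:
        if parse_month_day(self.window_start) == parse_month_day(self.window_end):
            raise InputError("window_start and window_end must differ")
        if not np.isfinite(self.critical_value):
            raise InputError("critical_value must be finite")
        if (self.rain_rule is not None) != (self.hazard_kind == "extreme_rainfall"):
            raise InputError(
                "rain_rule must be present exactly when hazard_kind is "
                "extreme_rainfall"
            )

    def resolve(self, season_year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Concrete window dates for a season year (cross-boundary windows
        belong to the season of their end date; 29 Feb clamps in non-leap
        years)."""
        return resolve_window(
            season_year,
            parse_month_day(self.window_start),
            parse_month_day(self.window_end),
        )


@dataclass(frozen=True)
class HazardAnnualResult:
    """Event-day count for one cell, season and hazard rule."""

    cell_id: str
    season_year: int
    crop_name: str
    hazard_kind: str
    event_days: int
    triggered: bool | None = None  # rain-rule hazards only


_BUILTIN_ROWS = (
    # crop, kind, variable, comparator, critical, start, end, rain rule
    ("chestnuts", "heat_stress", "tmax", ">", 40.0, "09-01", "11-30", None),
    ("chestnuts", "frost", "tmin", "<", -4.0, "09-15", "01-31", None),
    ("onions", "heat_stress", "tmax", ">", 31.0, "01-01", "02-29", None),
    ("onions", "frost", "tmin", "<", 0.0, "11-01", "11-30", None),
    ("onions", "extreme_rainfall", "precip", ">", 5.0, "01-01", "03-31",
     RainRule(k_days=4, span_days=7, min_daily_mm=5.0)),
    ("peas", "heat_stress", "tmax", ">", 30.0, "11-01", "02-29", None),
    ("peas", "frost", "tmin", "<", -2.0, "09-01", "11-30", None),
    ("potatoes", "heat_stress", "tmax", ">", 20.0, "11-01", "02-29", None),
    ("potatoes", "frost", "tmin", "<", 0.0, "11-01", "02-29", None),
    ("wheat", "heat_stress", "tmax", ">", 25.0, "10-15", "12-15", None),
    ("maize", "heat_stress", "tmax", ">", 30.0, "12-15", "02-15", None),
)


def builtin_hazard_specs() -> tuple[HazardSpec, ...]:
    """The eleven built-in crop hazard rules.

    The onion extreme-rainfall rule reads "more than 3 days in any 7 with
    >= 5 mm/day", i.e. at least 4 qualifying days in a 7-day span.
    """
    return tuple(
        HazardSpec(crop, kind, var, cmp_, crit, start, end, rule)
        for crop, kind, var, cmp_, crit, start, end, rule in _BUILTIN_ROWS
    )


def get_hazard_spec(crop_name: str, hazard_kind: str) -> HazardSpec:
    for spec in builtin_hazard_specs():
        if spec.crop_name == crop_name and spec.hazard_kind == hazard_kind:
            return spec
    raise InputError(f"no built-in spec for ({crop_name!r}, {hazard_kind!r})")


def specs_to_frame(specs: Iterable[HazardSpec]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of hazard specs."""
    rows = []
    for s in specs:
        rows.append(
            dict(
                crop_name=s.crop_name,
                hazard_kind=s.hazard_kind,
                variable=s.variable,
                comparator=s.comparator,
                critical_value=s.critical_value,
                window_start=s.window_start,
                window_end=s.window_end,
                rain_k_days=s.rain_rule.k_days if s.rain_rule else "",
                rain_span_days=s.rain_rule.span_days if s.rain_rule else "",
                rain_min_daily_mm=s.rain_rule.min_daily_mm if s.rain_rule else "",
            )
        )
    return pd.DataFrame(rows)


def specs_from_frame(df: pd.DataFrame) -> tuple[HazardSpec, ...]:
    out = []
    for _, row in df.iterrows():
        rule = None
        if row["hazard_kind"] == "extreme_rainfall":
            rule = RainRule(
                k_days=int(row["rain_k_days"]),
                span_days=int(row["rain_span_days"]),
                min_daily_mm=float(row["rain_min_daily_mm"]),
            )
        out.append(
            HazardSpec(
                crop_name=str(row["crop_name"]),
                hazard_kind=str(row["hazard_kind"]),
                variable=str(row["variable"]),
                comparator=str(row["comparator"]),
                critical_value=float(row["critical_value"]),
                window_start=str(row["window_start"]),
                window_end=str(row["window_end"]),
                rain_rule=rule,
            )
        )
    return tuple(out)


# ----------------------------------------------------------------------
def _exceeds(values: np.ndarray, comparator: str, critical: float) -> np.ndarray:
    return values > critical if comparator == ">" else values < critical


def count_hazard_days(
    series: DailyClimateSeries, spec: HazardSpec, season_year: int
) -> HazardAnnualResult:
    """Event days within the resolved sensitive window of one season.

    For threshold hazards, an event day strictly exceeds (or falls below)
    the critical value.  For the extreme-rainfall rule, event days are the
    days receiving at least the rule's daily amount, and ``triggered`` is
    true when some span of ``span_days`` consecutive days lying wholly
    inside the window contains at least ``k_days`` such days.
    """
    start, end = spec.resolve(season_year)
    if not series.covers(start, end):
        raise CoverageError(
            f"series {series.cell_id} does not cover {start.date()}..{end.date()}"
        )
    window = series.window(start, end)
    values = window[spec.variable].to_numpy()

    if spec.rain_rule is None:
        events = int(_exceeds(values, spec.comparator, spec.critical_value).sum())
        triggered = None
    else:
        rule = spec.rain_rule
        qualifying = values >= rule.min_daily_mm
        events = int(qualifying.sum())
        triggered = False
        if len(qualifying) >= rule.span_days:
            kernel = np.ones(rule.span_days, dtype=int)
            span_counts = np.convolve(qualifying.astype(int), kernel, mode="valid")
            triggered = bool((span_counts >= rule.k_days).any())
    return HazardAnnualResult(
        cell_id=series.cell_id,
        season_year=season_year,
        crop_name=spec.crop_name,
        hazard_kind=spec.hazard_kind,
        event_days=events,
        triggered=triggered,
    )


def seasons_available(series: DailyClimateSeries, spec: HazardSpec) -> list[int]:
    """Season years whose resolved window lies wholly inside the series
    (partial first/last seasons are dropped, not padded)."""
    years = series.years
    out = []
    for season in range(years[0], years[-1] + 2):
        start, end = spec.resolve(season)
        if series.covers(start, end):
            out.append(season)
    return out


def count_all_seasons(
    series_list: Sequence[DailyClimateSeries] | DailyClimateSeries,
    spec: HazardSpec,
    season_years: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Tidy frame of annual results across cells/members and seasons."""
    if isinstance(series_list, DailyClimateSeries):
        series_list = [series_list]
    rows = []
    for series in series_list:
        seasons = (
            seasons_available(series, spec)
            if season_years is None
            else list(season_years)
        )
        for season in seasons:
            res = count_hazard_days(series, spec, season)
            rows.append(
                dict(
                    cell_id=res.cell_id,
                    member_id=series.member_id,
                    season_year=res.season_year,
                    event_days=res.event_days,
                    triggered=res.triggered,
                )
            )
    return pd.DataFrame(rows)


def hazard_risk_change(
    baseline_results: pd.DataFrame, future_results: pd.DataFrame
) -> pd.Series:
    """Per-cell change in mean annual event days (future minus baseline).

    Inputs are tidy frames from :func:`count_all_seasons`; both must cover
    the same cells.  Positive values mean more hazard days per year.
    """
    for name, df in (("baseline", baseline_results), ("future", future_results)):
        if df.empty:
            raise InputError(f"{name} results are empty")
    b_cells = set(baseline_results["cell_id"])
    f_cells = set(future_results["cell_id"])
    if b_cells != f_cells:
        diff = sorted(b_cells.symmetric_difference(f_cells))
        raise AlignmentError(f"cells differ between baseline and future: {diff}")
    b_mean = baseline_results.groupby("cell_id")["event_days"].mean()
    f_mean = future_results.groupby("cell_id")["event_days"].mean()
    change = (f_mean - b_mean).rename("event_day_change")
    return change.sort_index()
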
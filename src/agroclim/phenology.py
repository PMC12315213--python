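"""Thermal-time crop phenology: GDD accumulation, stage progression,
maturity failure and stage-timing shifts.

Development is driven by growing degree-days computed with the simple
average method: ``max(0, min(T_mean, upper_cutoff) - base_temp)`` per day,
with ``T_mean = (tmin + tmax) / 2``.  Accumulated thermal time from sowing
is mapped onto the four-stage crop-coefficient scheme (initial,
development, mid-season, late-season) via strictly increasing stage
thresholds; crossing the final threshold before the season cutoff marks
maturity.  Seasons run July-June (southern hemisphere) and are labelled by
their harvest year.

Defaults for maize silage (base 8 degC, cutoff 30 degC, sowing 1 October,
stage thresholds 150/450/950/1350 degC day with stage coefficients
0.3/0.7/1.2/0.5) are conventional values for a temperate maize crop; they
are configurable and not calibrated to any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .calendars import parse_month_day, resolve_date, season_bounds
from .climate import DailyClimateSeries
from .errors import ConfigurationError, CoverageError, InputError

STAGE_NAMES = ("initial", "development", "mid_season", "late_season")


@dataclass(frozen=True)
class SowingRule:
    """Either a fixed month-day, or the earliest day on/after a month-day
    when the trailing mean temperature reaches a trigger."""

    kind: Literal["fixed", "temperature"] = "fixed"
    month_day: str = "10-01"  # fixed date, or earliest date for the trigger
    trigger_temp: float = 12.0  # degC, temperature rule only
    rolling_days: int = 10

    def __post_init__(self) -> None:
        parse_month_day(self.month_day)
        if self.kind not in ("fixed", "temperature"):
            raise ConfigurationError(f"unknown sowing rule kind {self.kind!r}")
        if self.rolling_days < 1:
            raise ConfigurationError("rolling_days must be >= 1")


@dataclass(frozen=True)
class CropPhenologyParams:
    """Thermal-time parameterisation of one crop."""

    crop_name: str
    base_temp: float
    upper_cutoff_temp: float | None = None
    sowing_rule: SowingRule = field(default_factory=SowingRule)
    #: accumulated degC day at each stage boundary: initial->development,
    #: ->mid, ->late, ->maturity (strictly increasing)
    stage_thresholds: tuple[float, ...] = (150.0, 450.0, 950.0, 1350.0)
    #: water-demand coefficient (Kc) per stage, same length as thresholds
    stage_kc: tuple[float, ...] = (0.3, 0.7, 1.2, 0.5)
    season_end_month_day: str = "06-30"

    def __post_init__(self) -> None:
        th = np.asarray(self.stage_thresholds, dtype=float)
        if len(th) < 1 or np.any(np.diff(th) <= 0) or th[0] <= 0:
            raise ConfigurationError("stage_thresholds must be positive and "
                                     "strictly increasing")
        if len(self.stage_kc) != len(th):
            raise ConfigurationError("stage_kc must match stage_thresholds length")
        if any(k <= 0 for k in self.stage_kc):
            raise ConfigurationError("stage_kc values must be positive")
        if (self.upper_cutoff_temp is not None
                and self.base_temp >= self.upper_cutoff_temp):
            raise ConfigurationError("base_temp must be below upper_cutoff_temp")
        parse_month_day(self.season_end_month_day)

    @property
    def maturity_threshold(self) -> float:
        return float(self.stage_thresholds[-1])

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = dict(
            crop_name=self.crop_name,
            base_temp=self.base_temp,
            upper_cutoff_temp=self.upper_cutoff_temp,
            sowing_rule=dict(
                kind=self.sowing_rule.kind,
                month_day=self.sowing_rule.month_day,
                trigger_temp=self.sowing_rule.trigger_temp,
                rolling_days=self.sowing_rule.rolling_days,
            ),
            stage_thresholds=list(self.stage_thresholds),
            stage_kc=list(self.stage_kc),
            season_end_month_day=self.season_end_month_day,
        )
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CropPhenologyParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rule = SowingRule(**doc.pop("sowing_rule", {}))
        doc["stage_thresholds"] = tuple(doc["stage_thresholds"])
        doc["stage_kc"] = tuple(doc["stage_kc"])
        return cls(sowing_rule=rule, **doc)


def maize_silage_params() -> CropPhenologyParams:
    """Conventional temperate maize-silage parameter set (not calibrated)."""
    return CropPhenologyParams(crop_name="maize_silage", base_temp=8.0,
                               upper_cutoff_temp=30.0)


# ----------------------------------------------------------------------
def daily_thermal_time(record, params: CropPhenologyParams):
    """Degree-days for one record (or arrays of tmin/tmax via a frame).

    ``max(0, min(T_mean, cutoff) - base)``; never negative.
    """
    tmean = 0.5 * (np.asarray(record.tmin) + np.asarray(record.tmax))
    return thermal_time_from_tmean(tmean, params)


def thermal_time_from_tmean(tmean, params: CropPhenologyParams):
    tmean = np.asarray(tmean, dtype=float)
    if params.upper_cutoff_temp is not None:
        tmean = np.minimum(tmean, params.upper_cutoff_temp)
    out = np.maximum(0.0, tmean - params.base_temp)
    return float(out) if out.ndim == 0 else out


@dataclass
class SeasonPhenology:
    """Daily development trace of one crop season at one cell."""

    season_year: int
    crop_name: str
    cell_id: str
    sowing_date: pd.Timestamp | None
    #: daily accumulated thermal time from the day after sowing, indexed by
    #: date up to maturity or the season cutoff; empty when never sown
    thermal_time: pd.Series
    #: stage index per day (0..len(thresholds); last value = mature)
    stage_index: pd.Series
    stage_entry_dates: dict[str, pd.Timestamp]
    maturity_reached: bool
    maturity_date: pd.Timestamp | None

    def stage_on(self, date: pd.Timestamp) -> int:
        return int(self.stage_index.loc[date])


def _resolve_sowing(
    series: DailyClimateSeries, params: CropPhenologyParams, season_year: int
) -> pd.Timestamp | None:
    rule = params.sowing_rule
    md = parse_month_day(rule.month_day)
    season_start, season_end = season_bounds(season_year)
    # month-days Jul-Dec belong to the preceding calendar year of the season
    year = season_year - 1 if md >= (7, 1) else season_year
    anchor = resolve_date(year, md)
    if rule.kind == "fixed":
        return anchor
    tmean = series.tmean.loc[season_start:season_end]
    rolled = tmean.rolling(rule.rolling_days, min_periods=rule.rolling_days).mean()
    eligible = rolled.loc[anchor:]
    hits = eligible[eligible >= rule.trigger_temp]
    return None if hits.empty else hits.index[0]


def run_season(
    series: DailyClimateSeries, params: CropPhenologyParams, season_year: int
) -> SeasonPhenology:
    """Develop one crop season: resolve sowing, accumulate thermal time
    from the day after sowing, track stage entries and maturity.

    A sowing rule that never triggers is a model outcome, not an error:
    the season is returned unsown with ``maturity_reached=False``.
    """
    season_start, _ = season_bounds(season_year)
    end_md = parse_month_day(params.season_end_month_day)
    season_end = resolve_date(
        season_year if end_md < (7, 1) else season_year - 1, end_md
    )
    if not series.covers(season_start, season_end):
        raise CoverageError(
            f"series {series.cell_id} does not cover season {season_year} "
            f"({season_start.date()}..{season_end.date()})"
        )

    empty = pd.Series(dtype=float)
    sowing = _resolve_sowing(series, params, season_year)
    if sowing is None or sowing >= season_end:
        return SeasonPhenology(
            season_year, params.crop_name, series.cell_id, None,
            empty, pd.Series(dtype=int), {}, False, None,
        )

    # accumulation starts the day after sowing (the planting day itself
    # contributes nothing), so constant forcing d reaches threshold H
    # exactly ceil(H/d) days after sowing
    window = series.window(sowing + pd.Timedelta(days=1), season_end)
    tmean = 0.5 * (window["tmin"].to_numpy() + window["tmax"].to_numpy())
    tt = np.cumsum(thermal_time_from_tmean(tmean, params))
    thresholds = np.asarray(params.stage_thresholds)
    stage = np.searchsorted(thresholds, tt, side="right")
    # side="right": reaching a threshold exactly enters the new stage, so the
    # stage index is the count of thresholds at or below the accumulation
    # (consistent with the inclusive maturity test below)

    mature = tt >= params.maturity_threshold
    if mature.any():
        cut = int(np.argmax(mature))  # first mature day; trace stops there
        idx = window.index[: cut + 1]
        maturity_date = window.index[cut]
        reached = True
    else:
        idx = window.index
        maturity_date = None
        reached = False
    tt_s = pd.Series(tt[: len(idx)], index=idx, name="thermal_time")
    stage_s = pd.Series(stage[: len(idx)], index=idx, name="stage_index")

    entries: dict[str, pd.Timestamp] = {}
    for i, name in enumerate(STAGE_NAMES[1:] + ("maturity",), start=1):
        reached_days = stage_s[stage_s >= i]
        if not reached_days.empty:
            entries[name] = reached_days.index[0]
    return SeasonPhenology(
        season_year, params.crop_name, series.cell_id, sowing,
        tt_s, stage_s, entries, reached, maturity_date,
    )


def seasons_available(
    series: DailyClimateSeries, params: CropPhenologyParams
) -> list[int]:
    """Season years fully covered by the series (July-June)."""
    years = series.years
    out = []
    for season in range(years[0], years[-1] + 2):
        start, _ = season_bounds(season)
        end_md = parse_month_day(params.season_end_month_day)
        end = resolve_date(season if end_md < (7, 1) else season - 1, end_md)
        if series.covers(start, end):
            out.append(season)
    return out


def maturity_failure_fraction(
    series: DailyClimateSeries,
    params: CropPhenologyParams,
    slice_years: tuple[int, int],
) -> float:
    """Fraction of seasons in [start, end] harvest years whose crop never
    reached maturity before the season cutoff."""
    start, end = slice_years
    seasons = [s for s in range(start, end + 1)]
    if len(seasons) < 2:
        raise InputError("slice must span at least 2 seasons")
    available = set(seasons_available(series, params))
    missing = [s for s in seasons if s not in available]
    if missing:
        raise CoverageError(f"series does not cover seasons {missing}")
    failed = sum(
        not run_season(series, params, s).maturity_reached for s in seasons
    )
    return failed / len(seasons)


def stage_timing_shift(
    baseline: Sequence[SeasonPhenology], future: Sequence[SeasonPhenology]
) -> pd.DataFrame:
    """Mean shift (days; negative = earlier) of each stage-entry date from
    a baseline to a future set of seasons.

    Timing is measured as days since the 1 July season start, so windows
    crossing the calendar-year boundary compare cleanly.  A stage reached
    in no season of one set is reported as NaN; other stages are
    unaffected.  Columns: ``shift_days``, ``sd_baseline``, ``sd_future``,
    ``n_baseline``, ``n_future``.
    """
    if not baseline or not future:
        raise InputError("both season sets must be non-empty")

    def day_of_season(ph: SeasonPhenology, stage: str) -> float | None:
        date = ph.stage_entry_dates.get(stage)
        if date is None:
            return None
        start, _ = season_bounds(ph.season_year)
        return float((date - start).days)

    rows = []
    for stage in STAGE_NAMES[1:] + ("maturity",):
        b = [d for ph in baseline if (d := day_of_season(ph, stage)) is not None]
        f = [d for ph in future if (d := day_of_season(ph, stage)) is not None]
        shift = float(np.mean(f) - np.mean(b)) if b and f else np.nan
        rows.append(
            dict(
                stage=stage,
                shift_days=shift,
                sd_baseline=float(np.std(b, ddof=1)) if len(b) > 1 else np.nan,
                sd_future=float(np.std(f, ddof=1)) if len(f) > 1 else np.nan,
                n_baseline=len(b),
                n_future=len(f),
            )
        )
    return pd.DataFrame(rows).set_index("stage")
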
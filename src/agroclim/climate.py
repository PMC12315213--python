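"""Daily climate series: the universal input to every risk model.

A :class:`DailyClimateSeries` wraps a pandas DataFrame of daily weather for
one grid cell under one scenario and one ensemble member.  The container
enforces the physical invariants every downstream model assumes: a gap-free
daily calendar covering whole years, ``tmax >= tmin``, non-negative
precipitation, radiation and wind, and relative humidity within [0, 100] %.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Required daily variables, in canonical column order.
VARIABLES = ("tmin", "tmax", "precip", "radiation", "rel_humidity", "wind")

#: CF-style units for each variable.
UNITS = {
    "tmin": "degC",
    "tmax": "degC",
    "precip": "mm/day",
    "radiation": "MJ/m2/day",
    "rel_humidity": "percent",
    "wind": "m/s",
}


@dataclass(frozen=True)
class DailyClimateRecord:
    """One day of weather at one cell."""

    date: pd.Timestamp
    tmin: float
    tmax: float
    precip: float
    radiation: float
    rel_humidity: float
    wind: float

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmin + self.tmax)


@dataclass
class DailyClimateSeries:
    """Date-ordered daily weather for one cell / scenario / member.

    Parameters
    ----------
    cell_id :
        Stable cell identifier (grid cells use ``"r{row}c{col}"``).
    latitude :
        Decimal degrees; negative in the southern hemisphere.
    data :
        DataFrame indexed by a daily DatetimeIndex with the columns in
        :data:`VARIABLES`.  Validated on construction.
    scenario_id, member_id :
        Provenance labels (RCP scenario and pseudo-GCM ensemble member).
    """

    cell_id: str
    latitude: float
    data: pd.DataFrame = field(repr=False)
    scenario_id: str = "observed"
    member_id: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValidationError("series data must be indexed by dates")
        missing = [v for v in VARIABLES if v not in df.columns]
        if missing:
            raise ValidationError(f"missing variable columns: {', '.join(missing)}")
        if len(df) == 0:
            raise ValidationError("series is empty")
        idx = df.index
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValidationError("dates must be strictly increasing")
        deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
        gaps = np.nonzero(deltas != 1)[0]
        if gaps.size:
            i = gaps[0]
            raise ValidationError(
                f"daily series has a gap after {idx[i].date()} "
                f"(next date {idx[i + 1].date()})"
            )
        first, last = idx[0], idx[-1]
        if (first.month, first.day) != (1, 1) or (last.month, last.day) != (12, 31):
            raise ValidationError(
                "series must cover whole calendar years "
                f"(runs {first.date()} to {last.date()})"
            )
        self._check_physical(df)

    @staticmethod
    def _check_physical(df: pd.DataFrame) -> None:
        if np.any(df["tmax"].to_numpy() < df["tmin"].to_numpy()):
            raise ValidationError("tmax < tmin on at least one day")
        for col, low, high in (
            ("precip", 0.0, None),
            ("radiation", 0.0, None),
            ("wind", 0.0, None),
            ("rel_humidity", 0.0, 100.0),
        ):
            vals = df[col].to_numpy()
            if np.any(~np.isfinite(vals)):
                raise ValidationError(f"{col} contains non-finite values")
            if np.any(vals < low):
                raise ValidationError(f"{col} below {low}")
            if high is not None and np.any(vals > high):
                raise ValidationError(f"{col} above {high}")

    # ------------------------------------------------------------------
    @property
    def years(self) -> list[int]:
        return sorted(set(self.data.index.year))

    @property
    def tmean(self) -> pd.Series:
        return 0.5 * (self.data["tmin"] + self.data["tmax"])

    def records(self) -> Iterator[DailyClimateRecord]:
        """Iterate the series day by day (convenience; vectorised paths
        operate on :attr:`data` directly)."""
        for date, row in self.data.iterrows():
            yield DailyClimateRecord(date=date, **{v: row[v] for v in VARIABLES})

    def window(self, start: pd.Timestamp, end: pd.Timestamp) -> pd.DataFrame:
        """Slice [start, end] inclusive without re-validating."""
        return self.data.loc[start:end]

    def covers(self, start: pd.Timestamp, end: pd.Timestamp) -> bool:
        return self.data.index[0] <= start and end <= self.data.index[-1]

    # ------------------------------------------------------------------
    def with_temperature_offset(self, offset: float) -> "DailyClimateSeries":
        """Copy with a uniform offset added to tmin and tmax (perturbation
        experiments; preserves all invariants)."""
        df = self.data.copy()
        df["tmin"] += offset
        df["tmax"] += offset
        return replace(self, data=df)

    def with_precip_scale(self, factor: float) -> "DailyClimateSeries":
        """Copy with precipitation multiplied by a non-negative factor."""
        if factor < 0:
            raise ValidationError("precip scale must be non-negative")
        df = self.data.copy()
        df["precip"] *= factor
        return replace(self, data=df)

    def subset_years(self, start_year: int, end_year: int) -> "DailyClimateSeries":
        """Whole-calendar-year slice [start_year, end_year]."""
        mask = (self.data.index.year >= start_year) & (self.data.index.year <= end_year)
        df = self.data.loc[mask]
        if df.empty:
            raise ValidationError(
                f"series has no data in {start_year}-{end_year} "
                f"(covers {self.years[0]}-{self.years[-1]})"
            )
        return replace(self, data=df)
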
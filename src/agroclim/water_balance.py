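"""Daily soil-water bucket and potential evapotranspiration deficit (PED).

A single plant-available store of size ``available_water_capacity`` is
driven by daily rain and stage-dependent crop water demand
``Kc x ET_ref``.  Actual evapotranspiration falls linearly below an
FAO-style stress threshold (fraction ``f`` of capacity, default 0.5) and is
additionally capped by the water physically available that day, so the
daily mass balance closes exactly::

    delta storage = precip [+ irrigation] - actual_et - drainage

The daily deficit ``demand - actual_et`` accumulates into the season PED,
the drought metric.  Reference ET defaults to Priestley-Taylor (radiation
and temperature only, keeping the model deliberately simple); an FAO-56
Penman-Monteith alternative using humidity and wind is available.

PED can be accumulated over the crop growth window (sowing to maturity,
following the staged phenology; the default) or over the whole July-June
season year with a constant coefficient (the classic fixed-coefficient
PED, used e.g. for pasture).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .calendars import parse_month_day, resolve_date, season_bounds, season_month_index
from .climate import DailyClimateSeries
from .errors import ConfigurationError, InputError
from .phenology import CropPhenologyParams, run_season

# psychrometric constant, kPa/degC (standard atmosphere)
_GAMMA = 0.0665
# latent heat of vaporisation, MJ/kg
_LAMBDA = 2.45
# Priestley-Taylor coefficient
_PT_ALPHA = 1.26
# reference-surface albedo and a flat net-longwave allowance, MJ/m2/day
_ALBEDO = 0.23
_NET_LONGWAVE = 1.5


@dataclass(frozen=True)
class SoilParams:
    """Plant-available water store of one cell."""

    cell_id: str
    available_water_capacity: float  # mm

    def __post_init__(self) -> None:
        if self.available_water_capacity <= 0:
            raise ConfigurationError("available_water_capacity must be > 0")


@dataclass(frozen=True)
class WaterBalanceState:
    """Store and fluxes after one daily step (all fluxes mm/day)."""

    date: pd.Timestamp | None
    soil_water: float
    pet: float = 0.0
    crop_demand: float = 0.0
    actual_et: float = 0.0
    drainage: float = 0.0
    daily_deficit: float = 0.0
    accumulated_ped: float = 0.0
    irrigation: float = 0.0


# ----------------------------------------------------------------------
# reference evapotranspiration
# ----------------------------------------------------------------------
def _svp(t):
    """Saturation vapour pressure (kPa) at temperature t (degC)."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def _svp_slope(t):
    return 4098.0 * _svp(t) / (t + 237.3) ** 2


def _net_radiation(radiation):
    return np.maximum(0.0, (1.0 - _ALBEDO) * radiation - _NET_LONGWAVE)


def reference_et_arrays(
    tmin, tmax, radiation, rel_humidity=None, wind=None,
    method: str = "priestley_taylor",
):
    """Vectorised reference ET (mm/day) from daily weather arrays."""
    tmean = 0.5 * (np.asarray(tmin, float) + np.asarray(tmax, float))
    rn = _net_radiation(np.asarray(radiation, float))
    delta = _svp_slope(tmean)
    if method == "priestley_taylor":
        et = _PT_ALPHA * delta / (delta + _GAMMA) * rn / _LAMBDA
    elif method == "penman_monteith":
        if rel_humidity is None or wind is None:
            raise InputError("penman_monteith needs rel_humidity and wind")
        es = 0.5 * (_svp(np.asarray(tmax, float)) + _svp(np.asarray(tmin, float)))
        ea = np.asarray(rel_humidity, float) / 100.0 * es
        u2 = np.asarray(wind, float)
        et = (0.408 * delta * rn
              + _GAMMA * 900.0 / (tmean + 273.0) * u2 * (es - ea)) / (
                  delta + _GAMMA * (1.0 + 0.34 * u2))
    else:
        raise InputError(f"unknown reference ET method {method!r}")
    return np.maximum(0.0, et)


def reference_et(record, latitude: float | None = None,
                 method: str = "priestley_taylor") -> float:
    """Reference ET (mm/day) for one daily record.

    Latitude is accepted for interface stability but the simplified net
    radiation derives from measured solar radiation alone.
    """
    return float(
        reference_et_arrays(
            record.tmin, record.tmax, record.radiation,
            rel_humidity=getattr(record, "rel_humidity", None),
            wind=getattr(record, "wind", None),
            method=method,
        )
    )


# ----------------------------------------------------------------------
# daily bucket step
# ----------------------------------------------------------------------
def _step(soil_water: float, pet: float, precip: float, kc: float,
          capacity: float, stress_fraction: float,
          irrigated: bool) -> tuple[float, float, float, float, float, float]:
    """Float kernel shared by step_day and the season runner.

    Returns (new_soil_water, demand, actual_et, drainage, deficit,
    irrigation)."""
    demand = kc * pet
    stress_store = stress_fraction * capacity
    supply_factor = 1.0 if soil_water >= stress_store else soil_water / stress_store
    aet = demand * supply_factor
    # cannot transpire more water than exists today (tiny stores)
    aet = min(aet, soil_water + precip)
    irrigation = 0.0
    if irrigated:
        irrigation = demand - aet
        aet = demand
    water = soil_water + precip + irrigation - aet
    drainage = max(0.0, water - capacity)
    water = min(water, capacity)
    deficit = demand - aet
    return water, demand, aet, drainage, deficit, irrigation


def step_day(
    state: WaterBalanceState,
    record,
    soil: SoilParams,
    kc: float,
    stress_fraction: float = 0.5,
    et_method: str = "priestley_taylor",
    irrigated: bool = False,
) -> WaterBalanceState:
    """Advance the bucket one day.

    Demand is ``kc x reference_et``; actual ET scales linearly once the
    store falls below ``stress_fraction`` of capacity and never exceeds
    the water available (store + rain).  Overflow beyond capacity leaves
    as drainage.  The unmet demand joins the accumulated PED.
    """
    if kc <= 0:
        raise InputError("kc must be > 0")
    pet = reference_et(record, method=et_method)
    water, demand, aet, drainage, deficit, irrigation = _step(
        state.soil_water, pet, record.precip, kc,
        soil.available_water_capacity, stress_fraction, irrigated,
    )
    return WaterBalanceState(
        date=getattr(record, "date", None),
        soil_water=water,
        pet=pet,
        crop_demand=demand,
        actual_et=aet,
        drainage=drainage,
        daily_deficit=deficit,
        accumulated_ped=state.accumulated_ped + deficit,
        irrigation=irrigation,
    )


# ----------------------------------------------------------------------
# season runs
# ----------------------------------------------------------------------
@dataclass
class SeasonWaterBalance:
    """Season PED plus the full daily trace."""

    season_year: int
    cell_id: str
    member_id: int
    crop_name: str
    ped: float  # mm, accumulated over the demand window
    trace: pd.DataFrame  # daily pet, crop_demand, actual_et, drainage,
    #                      daily_deficit, accumulated_ped, soil_water, irrigation


_TRACE_COLS = ("pet", "crop_demand", "actual_et", "drainage", "daily_deficit",
               "accumulated_ped", "soil_water", "irrigation")


def run_season_ped(
    series: DailyClimateSeries,
    params: CropPhenologyParams,
    soil: SoilParams,
    season_year: int,
    mode: Literal["growth", "calendar"] = "growth",
    constant_kc: float = 1.0,
    stress_fraction: float = 0.5,
    initial_fraction: float = 1.0,
    et_method: str = "priestley_taylor",
    irrigated: bool = False,
) -> SeasonWaterBalance:
    """Run the bucket over one July-June season year.

    ``growth`` mode follows the staged phenology: demand is zero outside
    the sowing-to-maturity window and ``Kc(stage) x ET_ref`` inside it, and
    the returned PED is the accumulation at maturity (or at the season
    cutoff when maturity is never reached).  ``calendar`` mode applies
    ``constant_kc`` on every day of the season year (the classic
    fixed-coefficient PED; phenology is not consulted).

    The store starts the season (1 July) at ``initial_fraction`` of
    capacity — full by default, a winter-recharge assumption.
    """
    if not 0.0 <= initial_fraction <= 1.0:
        raise InputError("initial_fraction must be in [0, 1]")
    season_start, _ = season_bounds(season_year)
    end_md = parse_month_day(params.season_end_month_day)
    season_end = resolve_date(
        season_year if end_md < (7, 1) else season_year - 1, end_md
    )
    window = series.window(season_start, season_end)

    if mode == "calendar":
        kc_arr = np.full(len(window), float(constant_kc))
        ped_mask = np.ones(len(window), dtype=bool)
        ped_end: pd.Timestamp | None = None
    elif mode == "growth":
        pheno = run_season(series, params, season_year)
        kc_arr = np.zeros(len(window))
        ped_mask = np.zeros(len(window), dtype=bool)
        if pheno.sowing_date is not None and len(pheno.stage_index):
            stage = pheno.stage_index.reindex(window.index)
            grow = stage.notna().to_numpy()
            idx = np.minimum(
                stage.fillna(0).to_numpy(dtype=int), len(params.stage_kc) - 1
            )
            kc_arr = np.where(grow, np.asarray(params.stage_kc)[idx], 0.0)
            ped_mask = grow
        ped_end = pheno.maturity_date
    else:
        raise InputError(f"unknown PED mode {mode!r}")

    pet = reference_et_arrays(
        window["tmin"].to_numpy(), window["tmax"].to_numpy(),
        window["radiation"].to_numpy(), window["rel_humidity"].to_numpy(),
        window["wind"].to_numpy(), method=et_method,
    )
    precip = window["precip"].to_numpy()
    capacity = soil.available_water_capacity

    n = len(window)
    cols = {c: np.zeros(n) for c in _TRACE_COLS}
    water = initial_fraction * capacity
    ped = 0.0
    for t in range(n):
        kc = kc_arr[t]
        if kc > 0.0:
            water, demand, aet, drain, deficit, irr = _step(
                water, pet[t], precip[t], kc, capacity, stress_fraction,
                irrigated,
            )
        else:
            # fallow day: no demand, rain still refills the store
            demand = aet = deficit = irr = 0.0
            water = water + precip[t]
            drain = max(0.0, water - capacity)
            water = min(water, capacity)
        if ped_mask[t]:
            ped += deficit
        cols["pet"][t] = pet[t]
        cols["crop_demand"][t] = demand
        cols["actual_et"][t] = aet
        cols["drainage"][t] = drain
        cols["daily_deficit"][t] = deficit
        cols["accumulated_ped"][t] = ped
        cols["soil_water"][t] = water
        cols["irrigation"][t] = irr

    trace = pd.DataFrame(cols, index=window.index)
    if ped_end is not None:
        final_ped = float(trace.loc[ped_end, "accumulated_ped"])
    else:
        final_ped = float(ped)
    return SeasonWaterBalance(
        season_year=season_year,
        cell_id=series.cell_id,
        member_id=series.member_id,
        crop_name=params.crop_name if mode == "growth" else f"constant_kc={constant_kc}",
        ped=final_ped,
        trace=trace,
    )


# ----------------------------------------------------------------------
# monthly demand profile
# ----------------------------------------------------------------------
def monthly_demand_profile(
    seasons: Sequence[SeasonWaterBalance],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean monthly crop water demand and the full year x member spread.

    Returns ``(summary, values)``: ``summary`` is indexed by calendar month
    1-12 with the across-seasons-and-members mean of monthly summed demand
    (months outside the growth period contribute 0); ``values`` holds one
    row per (month, season_year, member) — the individual points behind
    the mean.
    """
    if not seasons:
        raise InputError("at least one season trace is required")
    rows = []
    for s in seasons:
        monthly = s.trace["crop_demand"].groupby(s.trace.index.month).sum()
        for month in range(1, 13):
            rows.append(
                dict(
                    month=month,
                    season_year=s.season_year,
                    member_id=s.member_id,
                    cell_id=s.cell_id,
                    demand_mm=float(monthly.get(month, 0.0)),
                )
            )
    values = pd.DataFrame(rows)
    summary = (
        values.groupby("month")["demand_mm"]
        .agg(mean_demand_mm="mean", n="count")
        .reindex(range(1, 13), fill_value=0)
    )
    return summary, values


def demand_weighted_mean_month(summary: pd.DataFrame) -> float:
    """Demand-weighted mean month expressed on the season axis
    (July = 0 ... June = 11); smaller values mean demand peaks earlier in
    the season."""
    weights = summary["mean_demand_mm"].to_numpy()
    if weights.sum() <= 0:
        raise InputError("no demand in profile")
    positions = np.array([season_month_index(m) for m in summary.index])
    return float((weights * positions).sum() / weights.sum())
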
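"""Soil-water bucket: reference ET, exact mass balance, PED bounds and
monotonicity, and the monthly demand profile."""

import numpy as np
import pandas as pd
import pytest

from agroclim.climate import DailyClimateRecord
from agroclim.errors import InputError
from agroclim.phenology import CropPhenologyParams, maize_silage_params
from agroclim.water_balance import (
    SeasonWaterBalance,
    SoilParams,
    WaterBalanceState,
    demand_weighted_mean_month,
    monthly_demand_profile,
    reference_et,
    reference_et_arrays,
    run_season_ped,
    step_day,
)

from conftest import make_series


def record(tmin=12.0, tmax=25.0, precip=0.0, radiation=28.0, rh=60.0,
           wind=3.0):
    return DailyClimateRecord(
        date=pd.Timestamp("2000-01-15"), tmin=tmin, tmax=tmax, precip=precip,
        radiation=radiation, rel_humidity=rh, wind=wind,
    )


class TestReferenceEt:
    def test_zero_radiation_gives_near_zero_et(self):
        assert reference_et(record(radiation=0.0)) <= 0.1

    def test_doubling_radiation_strictly_increases_et(self):
        low = reference_et(record(radiation=12.0))
        high = reference_et(record(radiation=24.0))
        assert high > low

    def test_warming_does_not_decrease_et(self):
        cool = reference_et(record(tmin=5, tmax=15))
        warm = reference_et(record(tmin=15, tmax=25))
        assert warm >= cool

    def test_midsummer_day_in_sanity_band(self):
        """A clear mid-summer temperate day evaporates a handful of mm."""
        et = reference_et(record(tmin=12, tmax=25, radiation=28))
        assert 3.0 <= et <= 8.0

    def test_matches_independent_priestley_taylor(self):
        """Cross-check against a from-scratch evaluation of the published
        Priestley-Taylor form with the same radiation simplification."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            tmean = rng.uniform(0, 30)
            rs = rng.uniform(0, 35)
            es = 0.6108 * np.exp(17.27 * tmean / (tmean + 237.3))
            delta = 4098 * es / (tmean + 237.3) ** 2
            rn = max(0.0, 0.77 * rs - 1.5)
            expected = max(0.0, 1.26 * delta / (delta + 0.0665) * rn / 2.45)
            got = reference_et(record(tmin=tmean, tmax=tmean, radiation=rs))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_penman_monteith_available_and_positive(self):
        et = reference_et(record(), method="penman_monteith")
        assert et > 0.0

    def test_unknown_method_rejected(self):
        with pytest.raises(InputError, match="method"):
            reference_et_arrays(10, 20, 15, method="hargreaves")


class TestStepDay:
    SOIL = SoilParams("c", 100.0)

    def _state(self, water):
        return WaterBalanceState(date=None, soil_water=water)

    def test_saturated_soil_meets_demand_without_deficit(self):
        rec = record(radiation=28.0)
        pet = reference_et(rec)
        out = step_day(self._state(100.0), rec, self.SOIL, kc=1.0)
        assert out.actual_et == pytest.approx(pet)
        assert out.daily_deficit == pytest.approx(0.0)

    def test_empty_soil_no_rain_full_deficit(self):
        rec = record(radiation=28.0)
        out = step_day(self._state(0.0), rec, self.SOIL, kc=1.2)
        assert out.actual_et == 0.0
        assert out.daily_deficit == pytest.approx(out.crop_demand)

    def test_overflow_leaves_as_drainage(self):
        rec = record(precip=40.0, radiation=0.0)
        out = step_day(self._state(90.0), rec, self.SOIL, kc=1.0)
        assert out.soil_water == pytest.approx(100.0)
        assert out.drainage == pytest.approx(30.0)

    def test_stress_scaling_linear_below_threshold(self):
        rec = record(radiation=28.0)
        demand = reference_et(rec)
        out = step_day(self._state(25.0), rec, self.SOIL, kc=1.0)
        # store at 25% of capacity, stress threshold 50% -> half the demand
        assert out.actual_et == pytest.approx(0.5 * demand)

    def test_irrigated_mode_eliminates_deficit(self):
        rec = record(radiation=28.0)
        out = step_day(self._state(0.0), rec, self.SOIL, kc=1.0,
                       irrigated=True)
        assert out.daily_deficit == 0.0
        assert out.irrigation == pytest.approx(out.crop_demand)

    def test_mass_balance_closes_over_random_steps(self):
        """10,000 random daily steps: storage change equals
        precip + irrigation - actual ET - drainage to machine precision."""
        rng = np.random.default_rng(17)
        soil = SoilParams("c", 60.0)
        state = self._state(30.0)
        for i in range(10_000):
            rec = record(
                tmin=rng.uniform(-5, 20),
                tmax=rng.uniform(20, 35),
                precip=float(rng.gamma(0.7, 8.0)) if rng.random() < 0.3 else 0.0,
                radiation=rng.uniform(0, 35),
            )
            new = step_day(state, rec, soil, kc=rng.uniform(0.2, 1.3),
                           irrigated=bool(i % 7 == 0))
            residual = (new.soil_water - state.soil_water) - (
                rec.precip + new.irrigation - new.actual_et - new.drainage
            )
            assert abs(residual) < 1e-9
            assert 0.0 <= new.soil_water <= soil.available_water_capacity
            assert 0.0 <= new.actual_et <= new.crop_demand + 1e-12
            assert new.daily_deficit >= 0.0
            state = new


class TestSeasonPed:
    SOIL = SoilParams("test", 80.0)

    def test_daily_rain_meeting_demand_gives_zero_ped(self):
        series = make_series(start_year=2000, n_years=2, precip=30.0,
                             radiation=20.0)
        result = run_season_ped(series, maize_silage_params(), self.SOIL, 2001)
        assert result.ped == pytest.approx(0.0)

    def test_no_rain_empty_store_ped_equals_total_demand(self):
        series = make_series(start_year=2000, n_years=2, precip=0.0,
                             radiation=25.0)
        result = run_season_ped(
            series, maize_silage_params(), self.SOIL, 2001,
            initial_fraction=0.0,
        )
        total_demand = result.trace["crop_demand"].sum()
        assert total_demand > 0
        assert result.ped == pytest.approx(total_demand)

    def test_accumulated_ped_non_decreasing(self, cool_series):
        result = run_season_ped(cool_series, maize_silage_params(), self.SOIL,
                                2000)
        acc = result.trace["accumulated_ped"].to_numpy()
        assert (np.diff(acc) >= 0).all()

    def test_ped_monotone_under_precip_scaling(self, cool_series):
        params = maize_silage_params()
        peds = [
            run_season_ped(cool_series.with_precip_scale(f), params,
                           self.SOIL, 2002).ped
            for f in (1.0, 0.5, 0.25)
        ]
        assert peds[0] <= peds[1] <= peds[2]

    def test_ped_non_decreasing_in_kc(self, cool_series):
        base = maize_silage_params()
        thirstier = CropPhenologyParams(
            crop_name="maize_silage", base_temp=8.0, upper_cutoff_temp=30.0,
            stage_kc=tuple(k * 1.5 for k in base.stage_kc),
        )
        low = run_season_ped(cool_series, base, self.SOIL, 2002).ped
        high = run_season_ped(cool_series, thirstier, self.SOIL, 2002).ped
        assert high >= low

    def test_calendar_mode_matches_independent_fixed_kc_reimplementation(
        self, baseline_series
    ):
        """Classic constant-coefficient PED: the season runner agrees with a
        straightforward day-loop written independently here."""
        soil = SoilParams("r0c0", 70.0)
        kc, f = 1.0, 0.5
        result = run_season_ped(
            baseline_series, maize_silage_params(), soil, 2002,
            mode="calendar", constant_kc=kc,
        )
        window = baseline_series.window(
            pd.Timestamp(2001, 7, 1), pd.Timestamp(2002, 6, 30)
        )
        pet = reference_et_arrays(
            window["tmin"].to_numpy(), window["tmax"].to_numpy(),
            window["radiation"].to_numpy(),
        )
        water, ped = 70.0, 0.0
        for day in range(len(window)):
            demand = kc * pet[day]
            aet = demand * min(1.0, water / (f * 70.0))
            aet = min(aet, water + window["precip"].iloc[day])
            water = min(water + window["precip"].iloc[day] - aet, 70.0)
            ped += demand - aet
        assert result.ped == pytest.approx(ped, abs=1e-9)

    def test_irrigated_season_has_zero_ped_and_logs_depth(self, cool_series):
        result = run_season_ped(cool_series, maize_silage_params(), self.SOIL,
                                2002, irrigated=True)
        assert result.ped == pytest.approx(0.0)
        rainfed = run_season_ped(cool_series, maize_silage_params(), self.SOIL,
                                 2002)
        assert result.trace["irrigation"].sum() == pytest.approx(
            rainfed.ped, abs=1e-9
        )


class TestMonthlyDemand:
    def _constant_trace(self, season_year, member_id, demand):
        index = pd.date_range(f"{season_year - 1}-07-01",
                              f"{season_year}-06-30", freq="D")
        trace = pd.DataFrame(
            {"crop_demand": np.full(len(index), demand)}, index=index
        )
        return SeasonWaterBalance(season_year, "c", member_id, "x",
                                  ped=0.0, trace=trace)

    def test_constant_demand_month_sums(self):
        summary, _ = monthly_demand_profile([self._constant_trace(2001, 0, 2.0)])
        assert summary.loc[1, "mean_demand_mm"] == pytest.approx(31 * 2.0)
        assert summary.loc[2, "mean_demand_mm"] == pytest.approx(28 * 2.0)

    def test_spread_count_is_years_times_members(self):
        traces = [
            self._constant_trace(year, member, 1.0)
            for year in (2001, 2002, 2003)
            for member in (0, 1)
        ]
        _, values = monthly_demand_profile(traces)
        assert (values.groupby("month").size() == 6).all()

    def test_out_of_season_months_report_zero(self, cool_series):
        result = run_season_ped(cool_series, maize_silage_params(),
                                SoilParams("c", 80.0), 2002)
        summary, _ = monthly_demand_profile([result])
        assert summary.loc[8, "mean_demand_mm"] == 0.0  # August: pre-sowing

    def test_weighted_mean_month_earlier_for_earlier_demand(self):
        early = self._constant_trace(2001, 0, 0.0)
        early.trace.loc["2000-10-01":"2000-12-31", "crop_demand"] = 3.0
        late = self._constant_trace(2001, 0, 0.0)
        late.trace.loc["2001-01-01":"2001-03-31", "crop_demand"] = 3.0
        m_early = demand_weighted_mean_month(monthly_demand_profile([early])[0])
        m_late = demand_weighted_mean_month(monthly_demand_profile([late])[0])
        assert m_early < m_late
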
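"""Thermal-time engine: degree-day arithmetic, closed-form crossing times,
maturity failure and stage-timing shifts."""

import math

import numpy as np
import pandas as pd
import pytest

from agroclim.errors import ConfigurationError, CoverageError, InputError
from agroclim.phenology import (
    CropPhenologyParams,
    SowingRule,
    daily_thermal_time,
    maize_silage_params,
    maturity_failure_fraction,
    run_season,
    stage_timing_shift,
)

from conftest import make_series


def constant_params(thresholds=(150.0, 450.0, 950.0, 1350.0), base=8.0,
                    cutoff=30.0, **kwargs):
    return CropPhenologyParams(
        crop_name="maize_silage", base_temp=base, upper_cutoff_temp=cutoff,
        stage_thresholds=thresholds, **kwargs,
    )


def forcing_series(daily_tt, base=8.0, start_year=2000, n_years=2):
    """Constant series whose daily thermal time is exactly ``daily_tt``."""
    tmean = base + daily_tt
    return make_series(start_year=start_year, n_years=n_years,
                       tmin=tmean - 5, tmax=tmean + 5)


class TestDailyThermalTime:
    def test_simple_average_above_base(self):
        rec = make_series(tmin=10, tmax=20).records().__next__()
        assert daily_thermal_time(rec, constant_params()) == pytest.approx(7.0)

    def test_floor_at_zero_below_base(self):
        rec = next(make_series(tmin=0, tmax=10).records())
        assert daily_thermal_time(rec, constant_params()) == 0.0

    def test_upper_cutoff_caps_before_subtracting(self):
        rec = next(make_series(tmin=28, tmax=40).records())
        assert daily_thermal_time(rec, constant_params()) == pytest.approx(22.0)

    def test_never_negative(self):
        rng = np.random.default_rng(1)
        t = rng.normal(5, 15, 500)
        params = constant_params()
        vals = [
            daily_thermal_time(
                type("R", (), {"tmin": a, "tmax": a + 8})(), params
            )
            for a in t
        ]
        assert min(vals) >= 0.0


class TestParams:
    def test_thresholds_must_increase(self):
        with pytest.raises(ConfigurationError, match="increasing"):
            constant_params(thresholds=(150.0, 150.0, 900.0, 1350.0))

    def test_kc_length_must_match(self):
        with pytest.raises(ConfigurationError, match="stage_kc"):
            CropPhenologyParams("x", 8.0, stage_thresholds=(100.0, 200.0),
                                stage_kc=(0.3,))

    def test_yaml_round_trip(self, tmp_path):
        params = maize_silage_params()
        params.to_yaml(tmp_path / "maize.yaml")
        assert CropPhenologyParams.from_yaml(tmp_path / "maize.yaml") == params


class TestRunSeason:
    def test_zero_forcing_never_matures(self):
        series = forcing_series(0.0)
        result = run_season(series, constant_params(), 2001)
        assert not result.maturity_reached
        assert result.thermal_time.iloc[-1] == 0.0

    @pytest.mark.parametrize("daily_tt", [5.0, 7.5, 11.0, 15.0, 23.3])
    def test_constant_forcing_crossing_time_closed_form(self, daily_tt):
        """Maturity arrives exactly ceil(H/d) days after sowing."""
        series = forcing_series(daily_tt)
        params = constant_params(cutoff=None)  # keep the forcing truly constant
        result = run_season(series, params, 2001)
        expected_days = math.ceil(params.maturity_threshold / daily_tt)
        assert result.maturity_reached
        assert (result.maturity_date - result.sowing_date).days == expected_days

    def test_doubling_forcing_halves_crossing_time(self):
        params = constant_params()
        slow = run_season(forcing_series(6.0), params, 2001)
        fast = run_season(forcing_series(12.0), params, 2001)
        d_slow = (slow.maturity_date - slow.sowing_date).days
        d_fast = (fast.maturity_date - fast.sowing_date).days
        assert d_fast == math.ceil(d_slow / 2)  # exact up to ceiling rounding

    def test_fixed_sowing_rule_resolves_to_october_first(self):
        result = run_season(forcing_series(10.0), constant_params(), 2001)
        assert result.sowing_date == pd.Timestamp(2000, 10, 1)

    def test_stage_entries_ordered_and_monotone(self, cool_series):
        params = maize_silage_params()
        result = run_season(cool_series, params, 2000)
        tt = result.thermal_time.to_numpy()
        assert (np.diff(tt) >= 0).all()
        stages = result.stage_index.to_numpy()
        assert (np.diff(stages) >= 0).all()
        entries = [result.stage_entry_dates[s]
                   for s in ("development", "mid_season", "late_season")
                   if s in result.stage_entry_dates]
        assert entries == sorted(entries)

    def test_warming_never_delays_maturity(self, cool_series):
        params = maize_silage_params()
        for season in (1997, 2001, 2005):
            base = run_season(cool_series, params, season)
            warm = run_season(cool_series.with_temperature_offset(2.0),
                              params, season)
            if base.maturity_reached:
                assert warm.maturity_reached
                assert warm.maturity_date <= base.maturity_date

    def test_temperature_trigger_sowing(self):
        """A trigger rule sows on the first day the 10-day trailing mean
        reaches the trigger; here the ramp is constructed so that day is
        known."""
        n = 731
        tmean = np.full(n, 5.0)
        # season 2001: from 1 Oct 2000 (day-of-series 274) ramp up by 0.1/day
        ramp_start = 274
        tmean[ramp_start:] = 5.0 + 0.1 * np.arange(n - ramp_start)
        series = make_series(start_year=2000, n_years=2, tmin=tmean - 5,
                             tmax=tmean + 5)
        rule = SowingRule(kind="temperature", month_day="10-01",
                          trigger_temp=12.0, rolling_days=10)
        params = constant_params(sowing_rule=rule)
        result = run_season(series, params, 2001)
        # trailing mean over days k-9..k is 5 + 0.1 (k - 4.5) >= 12 at k = 75
        assert result.sowing_date == pd.Timestamp(2000, 10, 1) + pd.Timedelta(
            days=75
        )

    def test_trigger_never_firing_is_an_outcome_not_an_error(self):
        rule = SowingRule(kind="temperature", trigger_temp=40.0)
        series = forcing_series(5.0)
        result = run_season(series, constant_params(sowing_rule=rule), 2001)
        assert result.sowing_date is None
        assert not result.maturity_reached

    def test_uncovered_season_raises(self):
        series = forcing_series(10.0, n_years=1)
        with pytest.raises(CoverageError):
            run_season(series, constant_params(), 2001)


class TestMaturityFailure:
    def test_all_seasons_mature_gives_zero(self):
        series = forcing_series(15.0, n_years=6)
        assert maturity_failure_fraction(
            series, constant_params(), (2001, 2005)
        ) == 0.0

    def test_hand_counted_fraction(self):
        """Cold summers in exactly 5 of 20 seasons fail; fraction 0.25."""
        series = forcing_series(10.0, start_year=1999, n_years=22)
        cold_seasons = (2003, 2007, 2011, 2015, 2019)
        for season in cold_seasons:
            # freeze that season's growth window to zero forcing
            start = pd.Timestamp(season - 1, 7, 1)
            end = pd.Timestamp(season, 6, 30)
            series.data.loc[start:end, ["tmin", "tmax"]] = [3.0, 13.0]
        frac = maturity_failure_fraction(series, constant_params(),
                                         (2001, 2020))
        assert frac == pytest.approx(5 / 20)

    def test_short_slice_rejected(self):
        series = forcing_series(10.0, n_years=4)
        with pytest.raises(InputError, match="2 seasons"):
            maturity_failure_fraction(series, constant_params(), (2001, 2001))

    def test_warming_never_increases_failure(self, cool_series):
        params = maize_silage_params()
        base = maturity_failure_fraction(cool_series, params, (1997, 2015))
        warm = maturity_failure_fraction(
            cool_series.with_temperature_offset(1.5), params, (1997, 2015)
        )
        assert warm <= base


class TestStageTimingShift:
    def test_identical_inputs_shift_zero(self):
        series = forcing_series(9.0, n_years=4)
        params = constant_params()
        seasons = [run_season(series, params, s) for s in (2001, 2002, 2003)]
        shifts = stage_timing_shift(seasons, seasons)
        assert (shifts["shift_days"].dropna() == 0).all()

    def test_warming_advances_every_defined_stage(self, cool_series):
        params = maize_silage_params()
        seasons = range(1997, 2011)
        base = [run_season(cool_series, params, s) for s in seasons]
        warm_series = cool_series.with_temperature_offset(2.0)
        warm = [run_season(warm_series, params, s) for s in seasons]
        shifts = stage_timing_shift(base, warm)["shift_days"].dropna()
        assert not shifts.empty
        assert (shifts <= 0).all()

    def test_doubled_forcing_halves_crossing_day(self):
        params = constant_params()
        base = [run_season(forcing_series(6.0), params, 2001)]
        fast = [run_season(forcing_series(12.0), params, 2001)]
        shifts = stage_timing_shift(base, fast)
        d_base = (base[0].maturity_date - base[0].sowing_date).days
        d_fast = (fast[0].maturity_date - fast[0].sowing_date).days
        assert shifts.loc["maturity", "shift_days"] == pytest.approx(
            d_fast - d_base
        )
        assert d_fast == math.ceil(d_base / 2)

    def test_unreached_stage_reported_undefined(self):
        params = constant_params()
        matured = [run_season(forcing_series(10.0), params, 2001)]
        failed = [run_season(forcing_series(1.0), params, 2001)]
        shifts = stage_timing_shift(matured, failed)
        assert np.isnan(shifts.loc["maturity", "shift_days"])
        assert shifts.loc["development", "n_future"] == 1
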
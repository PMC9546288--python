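"""Season simulator and the CN / C-factor inverse calibration."""

import numpy as np
import pandas as pd
import pytest

from runoffmit.calibrate import (
    CalibrationError,
    calibrate_c_factor,
    calibrate_cn,
    calibrate_plot,
)
from runoffmit.cn_hydrology import WeatherSeries, runoff_depth
from runoffmit.season import runoff_sensitivity, simulate_season


def make_weather(precip):
    dates = pd.date_range("2019-04-01", periods=len(precip), freq="D")
    return WeatherSeries(dates, precip)


class TestSimulateSeason:
    def test_all_dry_season(self, plot_2018):
        res = simulate_season(make_weather([0.0] * 30), plot_2018)
        assert res.total_runoff_mm == 0.0
        assert res.total_erosion_kg_ha == 0.0
        assert res.n_runoff_events == 0

    def test_single_storm_matches_event_model(self, plot_2018):
        res = simulate_season(make_weather([26.0]), plot_2018.with_(curve_number=82))
        assert res.total_runoff_mm == pytest.approx(3.123, abs=1e-3)
        assert res.n_runoff_events == 1

    def test_totals_equal_daily_sums(self, wet_weather, plot_2018):
        res = simulate_season(wet_weather, plot_2018)
        assert res.total_runoff_mm == pytest.approx(res.daily["runoff_mm"].sum())
        assert res.total_erosion_kg_ha == pytest.approx(
            res.daily["soil_loss_kg_ha"].sum()
        )
        assert np.all(res.daily["runoff_mm"] <= res.daily["precip_mm"] + 1e-12)
        # soil loss strictly on runoff days
        dry = res.daily["runoff_mm"] == 0
        assert np.all(res.daily.loc[dry, "soil_loss_kg_ha"] == 0)

    def test_runoff_monotone_in_cn(self, wet_weather, plot_2018):
        totals = [
            simulate_season(wet_weather, plot_2018.with_(curve_number=cn)).total_runoff_mm
            for cn in [60, 69, 74, 79, 90, 100]
        ]
        assert np.all(np.diff(totals) > 0)

    def test_t_ha_view(self, wet_weather, plot_2018):
        res = simulate_season(wet_weather, plot_2018)
        assert res.total_erosion_t_ha == pytest.approx(
            res.total_erosion_kg_ha / 1000.0
        )


class TestSensitivityTable:
    def test_single_cn_equals_simulation(self, wet_weather, plot_2018):
        table = runoff_sensitivity(wet_weather, plot_2018, [plot_2018.curve_number])
        res = simulate_season(wet_weather, plot_2018)
        assert table.loc[0, "total_runoff_mm"] == pytest.approx(res.total_runoff_mm)

    def test_increasing_runoff_over_cn_grid(self, wet_weather, plot_2018):
        table = runoff_sensitivity(wet_weather, plot_2018, [69, 74, 79])
        assert table["total_runoff_mm"].is_monotonic_increasing
        assert table["total_runoff_mm"].nunique() == 3

    def test_erosion_proportional_to_c(self, wet_weather, plot_2018):
        cs = [11.2, 16.2, 21.2]
        totals = [
            simulate_season(wet_weather, plot_2018.with_(c_factor=c)).total_erosion_kg_ha
            for c in cs
        ]
        ratios = np.array(totals) / totals[0]
        assert ratios == pytest.approx(np.array(cs) / cs[0], rel=1e-12)

    def test_empty_grid_rejected(self, wet_weather, plot_2018):
        with pytest.raises(ValueError):
            runoff_sensitivity(wet_weather, plot_2018, [])


class TestCalibrateCn:
    def test_self_consistency(self, wet_weather, plot_2018):
        for cn0 in (68, 74, 83):
            target = simulate_season(
                wet_weather, plot_2018.with_(curve_number=cn0)
            ).total_runoff_mm
            assert calibrate_cn(wet_weather, plot_2018, target) == cn0

    def test_at_least_rule_rounds_up(self, wet_weather, plot_2018):
        lo = simulate_season(wet_weather, plot_2018.with_(curve_number=73)).total_runoff_mm
        hi = simulate_season(wet_weather, plot_2018.with_(curve_number=74)).total_runoff_mm
        target = 0.5 * (lo + hi)
        fitted, continuous = calibrate_cn(
            wet_weather, plot_2018, target, return_continuous=True
        )
        assert fitted == 74
        assert 73 < continuous < 74
        # the continuous fit reproduces the target exactly
        sim = simulate_season(
            wet_weather, plot_2018.with_(curve_number=continuous)
        ).total_runoff_mm
        assert sim == pytest.approx(target, abs=1e-4)

    def test_order_preserved(self, wet_weather, plot_2018):
        t74 = simulate_season(wet_weather, plot_2018.with_(curve_number=74)).total_runoff_mm
        fits = [calibrate_cn(wet_weather, plot_2018, t) for t in (0.3 * t74, t74, 2 * t74)]
        assert fits == sorted(fits)

    def test_unattainable_target(self, wet_weather, plot_2018):
        total_rain = wet_weather.precip_mm.sum()
        with pytest.raises(CalibrationError):
            calibrate_cn(wet_weather, plot_2018, total_rain + 1.0)

    def test_zero_target_returns_lower_bound(self, wet_weather, plot_2018):
        assert calibrate_cn(wet_weather, plot_2018, 0.0) == 30


class TestCalibrateC:
    def test_linearity_closed_form(self, wet_weather, plot_2018):
        base = simulate_season(
            wet_weather, plot_2018.with_(c_factor=1.0)
        ).total_erosion_kg_ha
        assert calibrate_c_factor(wet_weather, plot_2018, 2.0 * base) == pytest.approx(2.0)
        assert calibrate_c_factor(wet_weather, plot_2018, 0.0) == 0.0

    def test_recovery_to_machine_precision(self, wet_weather, plot_2018):
        true_c = 7.17
        measured = simulate_season(
            wet_weather, plot_2018.with_(c_factor=true_c)
        ).total_erosion_kg_ha
        fitted = calibrate_c_factor(wet_weather, plot_2018, measured)
        assert fitted == pytest.approx(true_c, rel=1e-12)
        resim = simulate_season(
            wet_weather, plot_2018.with_(c_factor=fitted)
        ).total_erosion_kg_ha
        assert resim == pytest.approx(measured, rel=1e-9)

    def test_no_erosive_events(self, plot_2018):
        dry = make_weather([1.0, 2.0, 0.5])  # all below Ia at CN 80
        assert runoff_depth(2.0, 80.0) == 0.0
        with pytest.raises(CalibrationError):
            calibrate_c_factor(dry, plot_2018, 100.0)


class TestCalibratePlot:
    def test_joint_sequence(self, wet_weather, plot_2018):
        truth = plot_2018.with_(curve_number=75, c_factor=7.14)
        season = simulate_season(wet_weather, truth)
        res = calibrate_plot(
            wet_weather,
            plot_2018,
            season.total_runoff_mm,
            season.total_erosion_kg_ha,
        )
        assert res.fitted_cn == 75
        assert res.fitted_c == pytest.approx(7.14, rel=1e-9)
        assert res.simulated_runoff_mm >= res.target_runoff_mm - 1e-9
        assert res.simulated_erosion_kg_ha == pytest.approx(
            res.target_erosion_kg_ha, rel=1e-9
        )
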
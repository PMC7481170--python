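"""Interpolation, drizzle accumulation, pressure/humidity conversions
and full forcing-table assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from ecoforce import forcing_builder as fb
from ecoforce.containers import GhgTable, ModelRun, WarmingWindow
from ecoforce.synthetic_weather import SyntheticClimateSpec, gen_station_obs, gen_subdaily


def _subdaily_frame(values, freq="3h", col="tmean"):
    index = pd.date_range("2050-01-01", periods=len(values), freq=freq)
    return pd.DataFrame({col: values}, index=index)


class TestLinearInterpolation:
    def test_knots_preserved_exactly(self, rng):
        frame = _subdaily_frame(rng.normal(10, 5, 16))
        out = fb.interpolate_linear(frame)
        knots = out.loc[frame.index, "tmean"]
        np.testing.assert_array_equal(knots.to_numpy(), frame["tmean"].to_numpy())

    def test_midpoint_between_knots(self):
        frame = _subdaily_frame([10.0, 16.0])
        out = fb.interpolate_linear(frame)
        assert out["tmean"].loc["2050-01-01 01:30:00"] == pytest.approx(13.0)

    def test_interior_points_match_two_point_line_oracle(self, rng):
        frame = _subdaily_frame(rng.normal(0, 1, 5))
        out = fb.interpolate_linear(frame)
        t0 = frame.index[0]
        for ts, value in out["tmean"].items():
            i = max(0, min(3, int((ts - t0) / pd.Timedelta("3h"))))
            expected = oracles.two_point_line(
                (frame.index[i] - t0).total_seconds(), frame["tmean"].iloc[i],
                (frame.index[i + 1] - t0).total_seconds(), frame["tmean"].iloc[i + 1],
                (ts - t0).total_seconds(),
            )
            assert value == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_linear_signal_exact_everywhere(self):
        frame = _subdaily_frame(np.arange(10.0) * 3.0)
        out = fb.interpolate_linear(frame)
        hours = (out.index - out.index[0]).total_seconds() / 3600
        np.testing.assert_allclose(out["tmean"].to_numpy(), hours, atol=1e-12)

    def test_irregular_input_rejected(self, rng):
        frame = _subdaily_frame(rng.normal(0, 1, 5)).drop(
            pd.Timestamp("2050-01-01 06:00:00")
        )
        with pytest.raises(ValueError, match="irregular"):
            fb.interpolate_linear(frame)


class TestPrecipDisaggregation:
    def test_uniform_split(self):
        precip = _subdaily_frame([3.0, 3.0], col="precip")["precip"]
        out = fb.disaggregate_precip(precip)
        assert len(out) == 12
        np.testing.assert_allclose(out.to_numpy(), 0.5)

    def test_zero_stays_zero(self):
        out = fb.disaggregate_precip(_subdaily_frame([0.0, 0.0], col="precip")["precip"])
        assert (out == 0.0).all()

    def test_conservation_per_knot(self, rng):
        precip = _subdaily_frame(rng.gamma(0.5, 2.0, 8), col="precip")["precip"]
        out = fb.disaggregate_precip(precip)
        sums = out.groupby(np.arange(len(out)) // 6).apply(
            lambda s: math.fsum(s.to_numpy())
        )
        np.testing.assert_allclose(sums.to_numpy(), precip.to_numpy(), atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fb.disaggregate_precip(_subdaily_frame([-1.0], col="precip")["precip"])


class TestDrizzleFilter:
    def test_hand_traced_accumulation(self):
        out, buffer = fb.drizzle_filter(np.array([0.4, 0.4, 0.4]))
        np.testing.assert_allclose(out, [0.0, 0.0, 1.2])
        assert buffer == 0.0

    def test_large_events_pass_unchanged(self):
        steps = np.array([1.0, 2.5, 1.1])
        out, buffer = fb.drizzle_filter(steps)
        np.testing.assert_array_equal(out, steps)
        assert buffer == 0.0

    def test_terminal_buffer_reported_and_conserved(self):
        out, buffer = fb.drizzle_filter(np.array([0.3, 0.3]))
        assert (out == 0.0).all()
        assert buffer == pytest.approx(0.6)
        assert math.fsum(out) + buffer == pytest.approx(0.6, abs=1e-15)

    def test_matches_hand_trace_oracle(self, rng):
        steps = rng.gamma(0.4, 0.6, 200)
        out, buffer = fb.drizzle_filter(steps)
        exp_out, exp_buffer = oracles.drizzle_trace(steps)
        np.testing.assert_allclose(out, exp_out, atol=1e-12)
        assert buffer == pytest.approx(exp_buffer, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), threshold=st.floats(0.5, 2.0))
    def test_no_event_below_threshold_and_mass_conserved(self, seed, threshold):
        steps = np.random.default_rng(seed).gamma(0.4, 0.6, 300)
        out, buffer = fb.drizzle_filter(steps, threshold)
        released = out[out > 0]
        assert (released >= threshold - 1e-12).all()
        assert buffer < threshold
        total_in = math.fsum(steps)
        assert abs(math.fsum(out) + buffer - total_in) <= 1e-12 * max(1.0, total_in)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            fb.drizzle_filter(np.array([0.1]), threshold=0.0)


class TestPressureReduction:
    def test_sea_level_identity(self):
        assert fb.surface_pressure_from_msl(101325.0, 15.0, elevation=0.0) == 101325.0

    def test_standard_atmosphere_example(self):
        # independent evaluation of p = mslp * exp(-g z / (Rd T))
        expected = 101325.0 * math.exp(-9.80665 * 43.0 / (287.05 * 288.15))
        p = fb.surface_pressure_from_msl(101325.0, 15.0, elevation=43.0)
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(100810, abs=15)

    def test_monotone_in_elevation(self):
        p1 = fb.surface_pressure_from_msl(101325.0, 15.0, elevation=10.0)
        p2 = fb.surface_pressure_from_msl(101325.0, 15.0, elevation=500.0)
        assert p2 < p1

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            fb.surface_pressure_from_msl(0.0, 15.0)


class TestHumidityConversion:
    def test_zero_specific_humidity_is_zero_rh(self):
        assert fb.relative_humidity_from_specific(0.0, 20.0, 101325.0) == 0.0

    def test_roundtrip_through_inverse(self):
        q = fb.specific_humidity_from_relative(60.0, 20.0, 101325.0)
        rh = fb.relative_humidity_from_specific(q, 20.0, 101325.0)
        assert rh == pytest.approx(60.0, abs=1e-6)

    def test_roundtrip_over_grid(self):
        rh_in = np.array([5.0, 40.0, 75.0, 99.0])
        for t in (-10.0, 0.0, 15.0, 30.0):
            for p in (95000.0, 101325.0):
                q = fb.specific_humidity_from_relative(rh_in, t, p)
                back = fb.relative_humidity_from_specific(q, t, p)
                np.testing.assert_allclose(back, rh_in, atol=1e-6)

    def test_supersaturation_clipped(self, caplog):
        q = fb.specific_humidity_from_relative(130.0, 20.0, 101325.0)
        with caplog.at_level("INFO", logger="ecoforce.forcing_builder"):
            rh = fb.relative_humidity_from_specific(q, 20.0, 101325.0)
        assert rh == 100.0
        assert "clipped" in caplog.text

    def test_negative_humidity_rejected(self):
        with pytest.raises(ValueError):
            fb.relative_humidity_from_specific(-0.001, 20.0, 101325.0)


@pytest.fixture(scope="module")
def run_and_ghg():
    daily = gen_station_obs(SyntheticClimateSpec(seed=12, n_years=4,
                                                 start_year=2050))
    sub = gen_subdaily(daily, seed=13)
    run = ModelRun(rcm_name="SYNRCM", gcm_name="SYNGCM", experiment="rcp85",
                   daily=daily, subdaily=sub)
    years = pd.Index(range(2050, 2055), name="year")
    ghg = GhgTable(pd.DataFrame(
        {"co2": 500.0 + 5.0 * np.arange(5), "ch4": 2000.0, "n2o": 340.0},
        index=years,
    ))
    return run, ghg


class TestAssembleForcing:
    def test_step_count_is_days_times_48(self, run_and_ghg):
        run, ghg = run_and_ghg
        window = WarmingWindow(2.0, 2051, 2051, 2052)
        table = fb.assemble_forcing(run, [window], ghg)[2.0]
        # 2051 (365 days) + 2052 (leap, 366 days), 48 half-hour steps/day
        assert len(table) == (365 + 366) * 48

    def test_precip_mass_balance_and_event_floor(self, run_and_ghg):
        run, ghg = run_and_ghg
        window = WarmingWindow(2.0, 2051, 2051, 2052)
        table = fb.assemble_forcing(run, [window], ghg)[2.0]
        years = run.subdaily.index.year
        total_in = math.fsum(run.subdaily.loc[(years >= 2051) & (years <= 2052),
                                              "precip"].to_numpy())
        total_out = math.fsum(table["precip"].to_numpy())
        buffer = table.attrs["drizzle_buffer_mm"]
        assert abs(total_out + buffer - total_in) <= 1e-12 * max(1.0, total_in)
        released = table["precip"][table["precip"] > 0]
        assert (released >= 1.0 - 1e-12).all()
        assert buffer < 1.0

    def test_temperature_passes_through_knots(self, run_and_ghg):
        run, ghg = run_and_ghg
        window = WarmingWindow(1.0, 2050, 2050, 2050)
        table = fb.assemble_forcing(run, [window], ghg)[1.0]
        knots = run.subdaily.loc["2050", "tmean"]
        np.testing.assert_array_equal(
            table.loc[knots.index, "tair"].to_numpy(), knots.to_numpy()
        )

    def test_ghg_stepwise_constant_per_year(self, run_and_ghg):
        run, ghg = run_and_ghg
        window = WarmingWindow(2.0, 2051, 2051, 2052)
        table = fb.assemble_forcing(run, [window], ghg)[2.0]
        assert (table.loc["2051", "co2"] == 505.0).all()
        assert (table.loc["2052", "co2"] == 510.0).all()

    def test_rh_comes_from_specific_humidity(self, run_and_ghg):
        run, ghg = run_and_ghg
        window = WarmingWindow(1.0, 2050, 2050, 2050)
        table = fb.assemble_forcing(run, [window], ghg)[1.0]
        assert table["relhum"].between(0, 100).all()
        # at knots the conversion must roundtrip the synthetic spechum
        knot = run.subdaily.index[5]
        q_back = fb.specific_humidity_from_relative(
            table.loc[knot, "relhum"], table.loc[knot, "tair"],
            table.loc[knot, "surf_pressure"],
        )
        assert q_back == pytest.approx(run.subdaily.loc[knot, "spechum"], rel=1e-6)

    def test_window_outside_coverage_named_in_error(self, run_and_ghg):
        run, ghg = run_and_ghg
        with pytest.raises(ValueError, match="2060"):
            fb.assemble_forcing(run, [WarmingWindow(3.0, 2060, 2060, 2061)], ghg)

    def test_missing_subdaily_rejected(self, run_and_ghg):
        run, ghg = run_and_ghg
        bare = ModelRun(rcm_name="X", gcm_name="Y", experiment="rcp85",
                        daily=run.daily)
        with pytest.raises(ValueError, match="no sub-daily"):
            fb.assemble_forcing(bare, [WarmingWindow(1.0, 2050, 2050, 2050)], ghg)
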
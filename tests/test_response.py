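"""Smoothing, FWHM block detection and dark-period profile metrics."""

import numpy as np
import pandas as pd
import pytest

from cagepulse import (
    LightSchedule,
    ValidationError,
    aggregate_responses,
    find_response,
    lights_off_profile,
    moving_average,
    responses_to_frame,
    smooth_series,
)

from conftest import START, brute_fwhm, minute_series

EVENT = START + pd.Timedelta(hours=6)


def _response(values, event=EVENT, window=(-3, 3), **kw):
    series = minute_series(values)
    smoothed = smooth_series(series)
    return find_response(
        smoothed, event,
        search_window=(pd.Timedelta(hours=window[0]),
                       pd.Timedelta(hours=window[1])), **kw)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        series = minute_series(np.full(200, 0.07))
        out = smooth_series(series)
        np.testing.assert_allclose(out.activity, 0.07)

    def test_impulse_spreads_to_plateau(self):
        x = np.zeros(200)
        x[100] = 1.0
        out = moving_average(x, 30)
        interior = out[90:110]
        assert np.isclose(interior.max(), 1 / 30)

    def test_rectangular_pulse_becomes_trapezoid(self):
        x = np.zeros(600)
        x[200:260] = 1.0  # 60-minute pulse
        out = moving_average(x, 30)
        assert np.isclose(out.max(), 1.0)  # plateau survives a 30-min window
        # ramps: value 0.5 appears mid-ramp
        assert (np.abs(out - 0.5) < 0.51 / 30).any()

    def test_missing_bins_excluded_from_windows(self):
        x = np.full(100, 0.2)
        x[50] = np.nan
        out = moving_average(x, 30)
        np.testing.assert_allclose(out, 0.2)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            smooth_series(minute_series([0.1]))


class TestFindResponse:
    def test_rect_pulse_fwhm_is_pulse_width(self):
        # 60-min unit pulse starting at the event; after 30-min smoothing the
        # supra-half-max block spans the pulse width within a minute
        values = np.zeros(720)
        event_idx = 360
        values[event_idx:event_idx + 60] = 1.0
        m = _response(values)
        assert abs(m.fwhm_duration - 60) <= 1
        assert np.isclose(m.peak_value, 1.0)
        assert 0 <= m.time_to_peak <= 60

    def test_four_minute_gap_merges_blocks(self):
        values = np.zeros(720)
        values[350:360] = 1.0
        values[364:374] = 0.9  # 4-minute dip between supra-half blocks
        series = minute_series(values)  # skip smoothing: test the block rule
        m = find_response(series, EVENT,
                          search_window=(pd.Timedelta(hours=-3),
                                         pd.Timedelta(hours=3)))
        assert m.fwhm_duration == 374 - 350

    def test_six_minute_gap_keeps_blocks_apart(self):
        values = np.zeros(720)
        values[350:360] = 0.9
        values[366:376] = 1.0  # max in second block
        m = find_response(minute_series(values), EVENT,
                          search_window=(pd.Timedelta(hours=-3),
                                         pd.Timedelta(hours=3)))
        assert m.fwhm_duration == 10
        assert m.time_to_peak == 366 - 360

    def test_five_minute_gap_does_not_merge(self):
        values = np.zeros(720)
        values[350:360] = 0.9
        values[365:375] = 1.0
        m = find_response(minute_series(values), EVENT,
                          search_window=(pd.Timedelta(hours=-3),
                                         pd.Timedelta(hours=3)))
        assert m.fwhm_duration == 10

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_block_enumerator(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 1, 360) ** 3
        values[rng.random(360) < 0.05] = np.nan
        m = find_response(minute_series(values), EVENT,
                          search_window=(pd.Timedelta(hours=-3),
                                         pd.Timedelta(hours=3)))
        peak_idx, start, stop = brute_fwhm(values[180:360 + 1])
        assert m.fwhm_duration == stop - start + 1
        assert m.time_to_peak == peak_idx - 180

    def test_shift_equivariance(self, rng):
        values = rng.uniform(0, 1, 720)
        m1 = _response(values)
        shift = pd.Timedelta(minutes=37)
        series2 = minute_series(values, start=START + shift)
        m2 = find_response(smooth_series(series2), EVENT + shift,
                           search_window=(pd.Timedelta(hours=-3),
                                          pd.Timedelta(hours=3)))
        assert m1.fwhm_duration == m2.fwhm_duration
        assert m1.time_to_peak == m2.time_to_peak
        assert m2.fwhm_interval[0] - m1.fwhm_interval[0] == shift

    def test_scale_invariance_of_times(self, rng):
        values = rng.uniform(0, 1, 720)
        m1 = _response(values)
        m2 = _response(5.0 * values)
        assert m1.time_to_peak == m2.time_to_peak
        assert m1.fwhm_duration == m2.fwhm_duration
        assert m1.time_to_p90 == m2.time_to_p90
        assert np.isclose(m2.peak_value, 5 * m1.peak_value)
        assert np.isclose(m2.average_in_fwhm, 5 * m1.average_in_fwhm)
        assert np.isclose(m2.value_p90, 5 * m1.value_p90)

    def test_metric_invariants(self, rng):
        for _ in range(20):
            values = rng.uniform(0, 1, 720)
            m = _response(values)
            t0, t1 = m.fwhm_interval
            assert t0 <= EVENT + pd.Timedelta(minutes=m.time_to_peak) <= t1
            assert m.average_in_fwhm <= m.peak_value + 1e-12
            assert 0 < m.value_p90 <= m.peak_value + 1e-12

    def test_all_missing_window_is_no_response(self):
        values = np.full(720, np.nan)
        values[:60] = 0.1  # keep the series itself non-degenerate
        m = find_response(minute_series(values), EVENT,
                          search_window=(pd.Timedelta(hours=-2),
                                         pd.Timedelta(hours=2)))
        assert m is None

    def test_fraction_of_peak_mode(self):
        values = np.zeros(720)
        values[300:420] = np.linspace(0, 1, 120)
        m = find_response(minute_series(values), EVENT,
                          search_window=(pd.Timedelta(hours=-3),
                                         pd.Timedelta(hours=3)),
                          p90_mode="fraction_of_peak")
        assert np.isclose(m.value_p90, 0.9 * m.peak_value)


class TestLightsOffProfile:
    def _series_with_nights(self, night_fn, n_days=3, day_level=0.01):
        schedule = LightSchedule()
        n = n_days * 1440
        values = np.full(n, day_level)
        idx_off = 12 * 60  # lights-off is 12 h after the 06:00 start
        for d in range(n_days):
            lo = d * 1440 + idx_off
            if lo + 720 <= n:
                values[lo:lo + 720] = night_fn(np.arange(720))
        return minute_series(values), schedule

    def test_monotone_ramp_peak_recovered(self):
        series, schedule = self._series_with_nights(
            lambda m: np.where(m <= 400, m / 400.0, (720 - m) / 320.0) + 0.01)
        prof = lights_off_profile(series, schedule)
        assert np.isclose(prof.trace.max(), 1.0)
        assert abs(prof.metrics.time_to_peak - 400) <= 15  # smoothing shift
        assert prof.n_periods >= 2

    def test_identical_weeks_equal_single_week(self):
        fn = lambda m: 0.02 + 0.1 * np.exp(-((m - 300) / 100.0) ** 2)
        series3, schedule = self._series_with_nights(fn, n_days=4)
        series1, _ = self._series_with_nights(fn, n_days=2)
        p3 = lights_off_profile(series3, schedule)
        p1 = lights_off_profile(series1, schedule)
        np.testing.assert_allclose(p3.trace, p1.trace, atol=1e-12)

    def test_zero_activity_nights_flagged(self):
        series, schedule = self._series_with_nights(lambda m: 0.0,
                                                    day_level=0.0)
        with pytest.raises(ValidationError, match="cannot normalise"):
            lights_off_profile(series, schedule)

    def test_normalised_maximum_is_exactly_one(self, rng):
        series, schedule = self._series_with_nights(
            lambda m: 0.02 + 0.001 * (m % 37))
        prof = lights_off_profile(series, schedule)
        assert prof.trace.max() == 1.0


class TestAggregate:
    def _frame(self):
        rows = []
        for week, peak in [(0, 0.1), (0, 0.1), (1, 0.2)]:
            rows.append({"cage_id": "C1", "week": week, "event_type": "x",
                         "event_time": None, "peak_value": peak,
                         "time_to_peak": 10.0, "fwhm_duration": 60.0,
                         "average_in_fwhm": peak / 2, "value_p90": peak,
                         "time_to_p90": 5.0})
        return pd.DataFrame(rows)

    def test_single_member_group_mean_is_value(self):
        out = aggregate_responses(self._frame(), keys=["week"])
        row = out[out["week"] == 1].iloc[0]
        assert row["peak_value_mean"] == 0.2
        assert row["peak_value_count"] == 1

    def test_identical_members_have_zero_sd(self):
        out = aggregate_responses(self._frame(), keys=["week"])
        row = out[out["week"] == 0].iloc[0]
        assert row["peak_value_std"] == 0.0

    def test_none_responses_dropped(self):
        frame = responses_to_frame([({"week": 0}, None)])
        assert frame.empty
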
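"""Activation detection, binning, spatial grouping and normalisation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from cagepulse import (
    ActivationSeries,
    ValidationError,
    activity_fraction,
    bin_activity,
    detect_activations,
    estimate_noise_threshold,
    normalize_activity,
    spatial_group,
)
from cagepulse.signal_io import InterventionCalendar, LightSchedule

from conftest import START, make_table, minute_series, naive_detect, \
    single_electrode_table


class TestDetect:
    def test_threshold_exceedance_yields_event(self):
        table = single_electrode_table([1.0, 1.0, 1.3])
        acts = detect_activations(table, threshold=0.2)
        assert list(acts.events[:, 0]) == [False, True]
        assert not acts.events[:, 1:].any()

    def test_constant_trace_never_fires(self):
        table = make_table(np.full((100, 12), 3.3))
        acts = detect_activations(table, threshold=1e-9)
        assert acts.events.sum() == 0

    def test_gaussian_noise_matches_analytic_tail(self, rng):
        # |X_t - X_{t-1}| with X ~ N(0, s^2) iid is Gaussian with sd s*sqrt(2);
        # theta = 4 s exceeds it with probability 2 Phi(-4/sqrt(2))
        sigma = 0.7
        table = make_table(rng.normal(0, sigma, (10_000, 12)))
        acts = detect_activations(table, threshold=4 * sigma)
        p = 2 * norm.cdf(-4 / np.sqrt(2))
        n = acts.valid.sum()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(acts.event_rate - p) < 3 * se

    def test_matches_naive_loop_with_gaps_and_nans(self, rng):
        n = 400
        times = START + pd.to_timedelta(
            np.cumsum(rng.choice([250, 250, 250, 1000], size=n)), unit="ms")
        values = rng.normal(0, 1, (n, 12))
        values[rng.random((n, 12)) < 0.02] = np.nan
        table = make_table(values, times=times)
        theta = rng.uniform(0.5, 2.0, 12)
        acts = detect_activations(table, threshold=theta)
        _, ev, va = naive_detect(table, theta)
        np.testing.assert_array_equal(acts.events, ev)
        np.testing.assert_array_equal(acts.valid, va)

    def test_raising_threshold_never_adds_events(self, rng):
        table = make_table(rng.normal(0, 1, (500, 12)))
        low = detect_activations(table, threshold=1.0)
        high = detect_activations(table, threshold=1.5)
        assert high.events.sum() <= low.events.sum()
        assert not (high.events & ~low.events).any()

    def test_all_gap_pairs_warn_empty(self):
        times = START + pd.to_timedelta([0, 10, 20], unit="s")
        table = make_table(np.ones((3, 12)), times=times)
        with pytest.warns(UserWarning, match="no valid"):
            acts = detect_activations(table, threshold=1.0)
        assert len(acts.pair_times) == 0


class TestNoiseThreshold:
    def test_mad_recovers_unit_difference_scale(self, rng):
        # random-walk signal: first differences are exactly the N(0,1) draws
        steps = rng.normal(0, 1, (20_000, 12))
        table = make_table(np.cumsum(steps, axis=0))
        theta = estimate_noise_threshold(table, k=4.0)
        np.testing.assert_allclose(theta, 4.0, rtol=0.05)

    def test_identical_traces_identical_thresholds(self, rng):
        trace = np.cumsum(rng.normal(0, 1, 500))
        values = np.tile(trace[:, None], (1, 12))
        theta = estimate_noise_threshold(make_table(values), k=4.0)
        assert np.all(theta == theta[0])

    def test_scale_equivariance(self, rng):
        values = np.cumsum(rng.normal(0, 1, (500, 12)), axis=0)
        t1 = estimate_noise_threshold(make_table(values), k=4.0)
        t2 = estimate_noise_threshold(make_table(2 * values), k=4.0)
        np.testing.assert_allclose(t2, 2 * t1, rtol=1e-12)

    def test_insufficient_data_names_electrode(self, rng):
        table = make_table(rng.normal(0, 1, (50, 12)))
        with pytest.raises(ValidationError, match="e01"):
            estimate_noise_threshold(table, k=4.0)


def _acts_from_events(events, start=START, period_ms=250, cage_id="T01"):
    events = np.asarray(events, dtype=bool)
    times = start + pd.to_timedelta(
        (1 + np.arange(len(events))) * period_ms, unit="ms")
    return ActivationSeries(cage_id=cage_id, pair_times=pd.DatetimeIndex(times),
                            events=events,
                            valid=np.ones_like(events, dtype=bool),
                            threshold_used=np.ones(12))


class TestBinning:
    def test_fully_sampled_minute_fraction(self):
        # 240 pair slots per electrode in a fully covered minute:
        # 288 events over 2880 slots -> activity 0.1
        events = np.zeros((480, 12), dtype=bool)
        flat = np.zeros(240 * 12, dtype=bool)
        flat[:288] = True
        events[240:] = flat.reshape(240, 12)
        acts = _acts_from_events(events)
        series = bin_activity(acts)
        full_minutes = series.df[series.df["valid_slots"] == 2880]
        assert np.isclose(full_minutes["activity"].iloc[0], 0.1)

    def test_zero_events_zero_activity(self):
        acts = _acts_from_events(np.zeros((480, 12), dtype=bool))
        series = bin_activity(acts)
        assert (series.df["activity"] == 0).all()

    def test_matches_per_bin_brute_force(self, rng):
        events = rng.random((3000, 12)) < 0.05
        acts = _acts_from_events(events)
        series = bin_activity(acts)
        # direct loop over bins
        minute = acts.pair_times.floor("min")
        for start, group in pd.DataFrame(
                {"m": minute}).groupby("m").groups.items():
            expect = events[np.asarray(group)].sum() / (len(group) * 12)
            got = series.df.loc[start, "activity"]
            assert np.isclose(got, expect)

    def test_empty_bins_are_missing_not_zero(self):
        # two bursts separated by a silent minute with no samples at all
        t1 = START + pd.to_timedelta(np.arange(10) * 250, unit="ms")
        t2 = START + pd.Timedelta(minutes=2) + pd.to_timedelta(
            np.arange(10) * 250, unit="ms")
        table = make_table(np.ones((20, 12)),
                           times=t1.append(t2))
        acts = detect_activations(table, threshold=0.5)
        series = bin_activity(acts)
        gap_bin = series.df.iloc[1]
        assert gap_bin["valid_slots"] == 0 and np.isnan(gap_bin["activity"])

    def test_day_night_and_cycle_labels(self):
        acts = _acts_from_events(np.zeros((480, 12), dtype=bool))
        calendar = InterventionCalendar(
            events=[("cage_change", START - pd.Timedelta(days=2))])
        series = bin_activity(acts, schedule=LightSchedule(),
                              calendar=calendar)
        assert (series.df["phase"] == "day").all()
        assert (series.df["week"] == 0).all()
        assert (series.df["cycle_day"] == 2).all()


class TestSpatialGrouping:
    def test_events_confined_to_front_electrodes(self, rng):
        events = np.zeros((1000, 12), dtype=bool)
        events[:, :3] = rng.random((1000, 3)) < 0.2
        fas = spatial_group(_acts_from_events(events))
        assert fas.areas["front"].df["events"].sum() == events.sum()
        for label in ("middle-front", "middle-rear", "rear"):
            assert fas.areas[label].df["events"].sum() == 0

    def test_uniform_events_give_identical_series(self):
        events = np.ones((1000, 12), dtype=bool)
        fas = spatial_group(_acts_from_events(events))
        ref = fas.areas["front"].df["activity"]
        for label, series in fas:
            pd.testing.assert_series_equal(series.df["activity"], ref)

    def test_weighted_mean_reconstructs_global(self, rng):
        events = rng.random((5000, 12)) < 0.1
        acts = _acts_from_events(events)
        fas = spatial_group(acts)
        rebuilt = fas.global_series()
        direct = bin_activity(acts)
        np.testing.assert_allclose(
            rebuilt.df["activity"].to_numpy(),
            direct.df["activity"].to_numpy(), atol=1e-12)


class TestNormalization:
    def test_constant_series_normalises_to_one(self):
        series = minute_series(np.full(120, 0.05), week=0)
        out = normalize_activity(series, window="cycle")
        np.testing.assert_allclose(out.activity, 1.0)

    def test_two_bin_window(self):
        series = minute_series([0.1, 0.3], week=0)
        out = normalize_activity(series, window="cycle")
        np.testing.assert_allclose(out.activity, [0.5, 1.5])

    def test_unit_mean_per_window(self, rng):
        values = rng.uniform(0, 0.2, 4 * 1440)
        week = np.repeat(np.arange(4), 1440)
        series = minute_series(values, week=week)
        out = normalize_activity(series, window="cycle")
        for w in range(4):
            assert abs(np.nanmean(out.activity[week == w]) - 1.0) < 1e-12

    def test_zero_window_marked_missing(self):
        values = np.concatenate([np.zeros(60), np.full(60, 0.1)])
        series = minute_series(values, week=np.repeat([0, 1], 60))
        out = normalize_activity(series, window="cycle")
        assert np.isnan(out.activity[:60]).all()
        assert np.isfinite(out.activity[60:]).all()


class TestFractions:
    def test_thirty_seventy_split(self):
        phase = np.array(["day"] * 720 + ["night"] * 720)
        values = np.concatenate([np.full(720, 30 / 720 / 2880),
                                 np.full(720, 70 / 720 / 2880)])
        series = minute_series(values, phase=phase)
        frac = activity_fraction(series, schedule=LightSchedule())
        assert np.isclose(frac.iloc[0]["day"], 30.0)
        assert np.isclose(frac.iloc[0]["night"], 70.0)

    def test_single_phase_takes_all(self):
        phase = np.array(["day"] * 720 + ["night"] * 720)
        values = np.concatenate([np.full(720, 0.1), np.zeros(720)])
        series = minute_series(values, phase=phase)
        frac = activity_fraction(series, schedule=LightSchedule())
        assert np.isclose(frac.iloc[0]["day"], 100.0)
        assert np.isclose(frac.iloc[0]["night"], 0.0)

    def test_fractions_sum_to_hundred(self, rng):
        phase = np.array((["day"] * 720 + ["night"] * 720) * 2)
        series = minute_series(rng.uniform(0, 0.2, 2880), phase=phase)
        frac = activity_fraction(series, schedule=LightSchedule())
        np.testing.assert_allclose(frac.sum(axis=1), 100.0, atol=1e-9)

    def test_eventless_day_is_undefined(self):
        phase = np.array(["day"] * 720 + ["night"] * 720)
        series = minute_series(np.zeros(1440), phase=phase)
        frac = activity_fraction(series, schedule=LightSchedule())
        assert frac.isna().all().all()
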
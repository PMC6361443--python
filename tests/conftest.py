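"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cagepulse import ActivationSeries, ActivityTimeSeries, SignalTable

START = pd.Timestamp("2023-01-05T06:00:00+00:00")  # a Thursday, lights-on


def make_table(values, cage_id="T01", start=START, period_ms=250,
               times=None) -> SignalTable:
    """SignalTable from an (n, 12) array on a regular 4 Hz grid."""
    values = np.asarray(values, dtype=float)
    if times is None:
        times = start + pd.to_timedelta(
            np.arange(len(values)) * period_ms, unit="ms")
    return SignalTable(cage_id=cage_id, time=pd.DatetimeIndex(times),
                       values=values)


def single_electrode_table(trace, electrode=0, fill=5.0, **kw) -> SignalTable:
    """Constant table with one electrode carrying the given trace."""
    trace = np.asarray(trace, dtype=float)
    values = np.full((len(trace), 12), fill)
    values[:, electrode] = trace
    return make_table(values, **kw)


def minute_series(values, cage_id="T01", start=START,
                  phase=None, week=None, cycle_day=None) -> ActivityTimeSeries:
    """Minute-binned ActivityTimeSeries from an activity vector."""
    values = np.asarray(values, dtype=float)
    idx = pd.DatetimeIndex(
        start + pd.to_timedelta(np.arange(len(values)), unit="min"),
        name="bin_start")
    slots = np.where(np.isfinite(values), 2880.0, 0.0)
    df = pd.DataFrame({
        "events": np.where(np.isfinite(values), values, 0.0) * slots,
        "valid_slots": slots,
        "activity": values,
    }, index=idx)
    if phase is not None:
        df["phase"] = phase
    if week is not None:
        df["week"] = week
    if cycle_day is not None:
        df["cycle_day"] = cycle_day
    df["day"] = idx.normalize()
    return ActivityTimeSeries(cage_id=cage_id,
                              bin_width=pd.Timedelta(minutes=1), df=df)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_detect(table: SignalTable, theta, max_pair_gap_ms=500):
    """Literal double loop over electrodes and sample pairs.

    Returns (pair kept mask over consecutive rows, events, valid) with the
    same pair-retention convention as the pipeline: a pair exists only when
    the two samples are at most max_pair_gap apart; validity additionally
    requires finite readings at both ends.
    """
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (12,))
    n = len(table)
    kept, events, valid = [], [], []
    for i in range(1, n):
        gap_ms = (table.time[i] - table.time[i - 1]) / pd.Timedelta(
            milliseconds=1)
        if gap_ms > max_pair_gap_ms:
            continue
        kept.append(i)
        ev_row, va_row = [], []
        for e in range(12):
            a, b = table.values[i - 1, e], table.values[i, e]
            ok = np.isfinite(a) and np.isfinite(b)
            va_row.append(ok)
            ev_row.append(bool(ok and abs(b - a) > theta[e]))
        events.append(ev_row)
        valid.append(va_row)
    return (np.array(kept, dtype=int),
            np.array(events, dtype=bool).reshape(-1, 12),
            np.array(valid, dtype=bool).reshape(-1, 12))


def brute_fwhm(values, merge_gap=5):
    """Literal supra-half-max block enumeration with the merge rule.

    Enumerates every maximal run of minutes strictly above half the peak,
    merges consecutive runs separated by fewer than ``merge_gap`` minutes,
    and returns (peak index, start, stop) of the merged run containing the
    first maximum, or None if the window holds no finite value.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        return None
    peak_idx = int(np.nanargmax(values))
    half = values[peak_idx] / 2.0
    runs = []
    i = 0
    n = len(values)
    while i < n:
        if finite[i] and values[i] > half:
            j = i
            while j + 1 < n and finite[j + 1] and values[j + 1] > half:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    for start, stop in merged:
        if start <= peak_idx <= stop:
            return peak_idx, start, stop
    return None


@pytest.fixture
def rng():
    return np.random.default_rng(20230105)
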
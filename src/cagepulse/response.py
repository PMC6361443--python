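"""Event-locked response quantification (FWHM paradigm).

A response to lights-on, lights-off or a cage-change is delineated from
baseline variation as follows: smooth the minute-based global activity
series with a 30-minute moving average, find the peak within an
event-specific search window, collect the contiguous blocks of minutes whose
activity is strictly larger than half the peak, merge blocks separated by
less than 5 minutes, and keep the block containing the maximum.  The block's
extent is the response duration (FWHM); the mean of the smoothed trace over
the block is the average activity during the response.

The dark-period profile metrics additionally report the time to peak and a
90th-percentile value/time computed on the week-averaged, peak-normalised
720-minute trace starting at lights-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import ActivityTimeSeries
from .signal_io import LightSchedule, ValidationError

__all__ = [
    "ResponseMetrics",
    "LightsOffProfile",
    "smooth_series",
    "moving_average",
    "find_response",
    "lights_off_profile",
    "aggregate_responses",
    "responses_to_frame",
    "DEFAULT_SEARCH_WINDOWS",
]

#: Event-specific default search windows (pre, post) relative to the event.
DEFAULT_SEARCH_WINDOWS: dict[str, tuple[pd.Timedelta, pd.Timedelta]] = {
    "lights_on": (pd.Timedelta(hours=-3), pd.Timedelta(hours=3)),
    "lights_off": (pd.Timedelta(0), pd.Timedelta(minutes=720)),
    "cage_change": (pd.Timedelta(0), pd.Timedelta(hours=6)),
}


@dataclass
class ResponseMetrics:
    """Metrics of one event-locked response.

    Times are minutes relative to the event; values are in activity units
    (fraction of electrode-pair slots active, or normalised units when the
    input trace was normalised).
    """

    event_type: str
    event_time: pd.Timestamp | None
    peak_value: float
    time_to_peak: float
    fwhm_duration: float
    fwhm_interval: tuple[pd.Timestamp, pd.Timestamp] | tuple[float, float]
    average_in_fwhm: float
    value_p90: float
    time_to_p90: float


@dataclass
class LightsOffProfile:
    """Week-averaged, peak-normalised dark-period activity trace."""

    trace: np.ndarray  # (720,) normalised smoothed activity, max = 1.0
    metrics: ResponseMetrics
    n_periods: int
    period_starts: pd.DatetimeIndex


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with truncated edge windows, NaN-aware.

    The window at index ``i`` covers ``[i - n//2, i + n - n//2 - 1]``
    clipped to the array; missing (NaN) bins are excluded from each
    window's mean.  Windows containing no finite value yield NaN.
    """
    x = np.asarray(x, dtype=float)
    half_l = n // 2
    half_r = n - half_l - 1
    finite = np.isfinite(x)
    v = np.where(finite, x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    ccnt = np.concatenate([[0.0], np.cumsum(finite.astype(float))])
    i = np.arange(len(x))
    lo = np.clip(i - half_l, 0, len(x))
    hi = np.clip(i + half_r + 1, 0, len(x))
    tot = csum[hi] - csum[lo]
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return out


def smooth_series(
    series: ActivityTimeSeries,
    window: pd.Timedelta = pd.Timedelta(minutes=30),
) -> ActivityTimeSeries:
    """30-minute (default) moving-average low-pass of a minute series."""
    if series.bin_width != pd.Timedelta(minutes=1):
        raise ValidationError("smoothing expects a 1-minute binned series")
    if len(series) < 2:
        raise ValidationError("series too short to smooth")
    n = int(round(window / series.bin_width))
    df = series.df.copy()
    df["activity"] = moving_average(series.activity, n)
    return ActivityTimeSeries(series.cage_id, series.bin_width, df)


# ---------------------------------------------------------------------------
# FWHM block algorithm
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, stop) index pairs."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def _fwhm_block(
    values: np.ndarray, merge_gap: int = 5
) -> tuple[int, int, int] | None:
    """(peak index, block start, block stop) of the supra-half-max block.

    Blocks are runs of minutes strictly above half the window peak; runs
    separated by fewer than ``merge_gap`` minutes are merged; the block
    containing the (first) maximum is returned.
    """
    if not np.isfinite(values).any():
        return None
    peak_idx = int(np.nanargmax(values))
    half = values[peak_idx] / 2.0
    with np.errstate(invalid="ignore"):
        above = values > half
    blocks = _runs(above)
    if not blocks:
        return None
    merged = [blocks[0]]
    for start, stop in blocks[1:]:
        prev_start, prev_stop = merged[-1]
        if start - prev_stop - 1 < merge_gap:
            merged[-1] = (prev_start, stop)
        else:
            merged.append((start, stop))
    for start, stop in merged:
        if start <= peak_idx <= stop:
            return peak_idx, start, stop
    return None  # unreachable: the peak minute is always above half


def _window_metrics(
    values: np.ndarray,
    minutes: np.ndarray,
    event_type: str,
    event_time,
    merge_gap: int,
    p90_mode: str,
    interval_times=None,
) -> ResponseMetrics | None:
    block = _fwhm_block(values, merge_gap)
    if block is None:
        return None
    peak_idx, start, stop = block
    peak = float(values[peak_idx])
    p90 = (float(np.nanpercentile(values, 90)) if p90_mode == "distribution"
           else 0.9 * peak)
    with np.errstate(invalid="ignore"):
        reach = np.nonzero(values >= p90)[0]
    t_p90 = float(minutes[reach[0]]) if reach.size else np.nan
    if interval_times is not None:
        interval = (interval_times[start], interval_times[stop])
    else:
        interval = (float(minutes[start]), float(minutes[stop]))
    return ResponseMetrics(
        event_type=event_type,
        event_time=event_time,
        peak_value=peak,
        time_to_peak=float(minutes[peak_idx]),
        fwhm_duration=float(minutes[stop] - minutes[start] + 1),
        fwhm_interval=interval,
        average_in_fwhm=float(np.nanmean(values[start:stop + 1])),
        value_p90=p90,
        time_to_p90=t_p90,
    )


def find_response(
    smoothed: ActivityTimeSeries,
    event_time: pd.Timestamp,
    search_window: tuple[pd.Timedelta, pd.Timedelta] | None = None,
    merge_gap: int = 5,
    event_type: str = "event",
    p90_mode: str = "distribution",
) -> ResponseMetrics | None:
    """Quantify the response to one event on a smoothed minute series.

    The search window defaults to the event-type specific convention
    (lights-on +/- 3 h; lights-off the full 720-minute dark period;
    cage-change 6 h after the event).  Returns ``None`` when the window
    holds no finite activity (no-response sentinel).

    ``p90_mode='distribution'`` reports the 90th percentile of the smoothed
    values in the window; ``'fraction_of_peak'`` reports 0.9 x peak.  The
    time to p90 is the first minute at or above that level.
    """
    if smoothed.bin_width != pd.Timedelta(minutes=1):
        raise ValidationError("find_response expects a 1-minute series")
    if search_window is None:
        search_window = DEFAULT_SEARCH_WINDOWS.get(
            event_type, (pd.Timedelta(hours=-3), pd.Timedelta(hours=3)))
    pre, post = search_window
    idx = smoothed.bin_start
    sel = (idx >= event_time + pre) & (idx <= event_time + post)
    if not sel.any():
        raise ValidationError("search window outside the series support")
    values = smoothed.activity[sel]
    times = idx[sel]
    minutes = (times - event_time) / pd.Timedelta(minutes=1)
    metrics = _window_metrics(
        values, np.asarray(minutes), event_type, event_time, merge_gap,
        p90_mode, interval_times=times)
    return metrics


# ---------------------------------------------------------------------------
# dark-period profile
# ---------------------------------------------------------------------------

def lights_off_profile(
    series: ActivityTimeSeries,
    schedule: LightSchedule,
    weeks: list[int] | None = None,
    smooth_window: int = 30,
    merge_gap: int = 5,
    p90_mode: str = "distribution",
) -> LightsOffProfile:
    """Average dark-period trace across weeks, normalised to peak = 1.0.

    For every complete 720-minute dark period (optionally restricted to the
    given cage-change-cycle indices), the raw minute trace is extracted from
    lights-off, averaged across periods, smoothed with a 30-minute moving
    average and scaled so its maximum is exactly 1.0.  Metrics (time to
    peak, p90, FWHM) are computed on this averaged smoothed trace over the
    full dark period.
    """
    if series.bin_width != pd.Timedelta(minutes=1):
        raise ValidationError("profile expects a 1-minute binned series")
    night_min = int(schedule.night_length / pd.Timedelta(minutes=1))
    idx = series.bin_start
    if len(idx) == 0:
        raise ValidationError("empty series")
    offs = schedule.transitions(idx[0], idx[-1], which="lights_off")
    starts = []
    rows = []
    lookup = series.df["activity"]
    weeks_col = series.df["week"] if "week" in series.df.columns else None
    for t in offs:
        grid = t + pd.to_timedelta(np.arange(night_min), unit="min")
        if grid[0] < idx[0] or grid[-1] > idx[-1]:
            continue
        if weeks is not None and weeks_col is not None:
            pos = series.df.index.get_indexer([t])
            if pos[0] < 0 or int(weeks_col.iloc[pos[0]]) not in weeks:
                continue
        vals = lookup.reindex(grid).to_numpy(dtype=float)
        rows.append(vals)
        starts.append(t)
    if not rows:
        raise ValidationError("no complete dark period in the series")
    mat = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(mat, axis=0)
    smoothed = moving_average(avg, smooth_window)
    peak = np.nanmax(smoothed)
    if not np.isfinite(peak) or peak <= 0:
        raise ValidationError("zero-activity dark periods: cannot normalise")
    trace = smoothed / peak
    minutes = np.arange(night_min, dtype=float)
    metrics = _window_metrics(
        trace, minutes, "lights_off", starts[0], merge_gap, p90_mode)
    return LightsOffProfile(
        trace=trace,
        metrics=metrics,
        n_periods=len(rows),
        period_starts=pd.DatetimeIndex(starts),
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

_METRIC_FIELDS = ["peak_value", "time_to_peak", "fwhm_duration",
                  "average_in_fwhm", "value_p90", "time_to_p90"]


def responses_to_frame(items) -> pd.DataFrame:
    """Tidy one-row-per-response table from (keys, ResponseMetrics) pairs.

    ``items`` is an iterable of ``(key_dict, ResponseMetrics)`` or bare
    ``ResponseMetrics``; ``None`` responses (no-response sentinel) are
    dropped.
    """
    records = []
    for item in items:
        keys, m = item if isinstance(item, tuple) else ({}, item)
        if m is None:
            continue
        rec = dict(keys)
        rec["event_type"] = m.event_type
        rec["event_time"] = m.event_time
        for f in _METRIC_FIELDS:
            rec[f] = getattr(m, f)
        records.append(rec)
    return pd.DataFrame(records)


def aggregate_responses(
    responses: pd.DataFrame | list,
    keys: list[str],
    quantiles: tuple[float, ...] = (),
) -> pd.DataFrame:
    """Grouped means/SDs/counts of response metrics.

    Groups with no responses are absent from the output, never zero-filled.
    """
    frame = (responses if isinstance(responses, pd.DataFrame)
             else responses_to_frame(responses))
    if frame.empty:
        return frame
    aggs: list = ["mean", "std", "count"]
    for q in quantiles:
        aggs.append(("q%g" % (100 * q), lambda s, q=q: s.quantile(q)))
    grouped = frame.groupby(keys, observed=True)[_METRIC_FIELDS].agg(aggs)
    grouped.columns = ["_".join(c) for c in grouped.columns]
    return grouped.reset_index()
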
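"""From raw capacitance to activation events and binned activity.

The basic activity metric is the first-order difference of the raw signal:
for each electrode, the absolute difference between two successive 250 ms
samples is compared against a noise threshold, and each exceedance is one
*activation* (activity event).  Binned activity is the fraction of valid
electrode-sample-pair slots in a bin that carry an event, which is bounded
in [0, 1] and pools the 12 electrodes of a cage into a single cage-level
(global) measure.

Differencing never spans recording gaps: a sample pair exists only where the
two samples are at most ``max_pair_gap`` apart (default twice the sampling
period), and pairs touching non-finite readings are excluded from both the
numerator and the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signal_io import (
    N_ELECTRODES,
    DetectionPolicy,
    ElectrodeLayout,
    InterventionCalendar,
    LightSchedule,
    SignalTable,
    ValidationError,
)

__all__ = [
    "ActivationSeries",
    "ActivityTimeSeries",
    "FloorAreaSeries",
    "detect_activations",
    "estimate_noise_threshold",
    "bin_activity",
    "spatial_group",
    "normalize_activity",
    "activity_fraction",
]

MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma for Gaussian noise


@dataclass
class ActivationSeries:
    """Boolean activity events on sample-pair ticks, one column per electrode.

    ``pair_times`` holds the instant of the *later* sample of each retained
    consecutive pair (pairs spanning gaps larger than ``max_pair_gap`` are
    dropped entirely); ``valid`` marks, per electrode, pairs with finite
    readings at both samples; ``events`` is True only on valid pairs.
    """

    cage_id: str
    pair_times: pd.DatetimeIndex
    events: np.ndarray  # (n_pairs, 12) bool
    valid: np.ndarray  # (n_pairs, 12) bool
    threshold_used: np.ndarray  # (12,)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.threshold_used = np.broadcast_to(
            np.asarray(self.threshold_used, dtype=float), (N_ELECTRODES,)
        ).copy()
        if self.events.shape != self.valid.shape:
            raise ValidationError("events/valid shape mismatch")
        if self.events[~self.valid].any():
            raise ValidationError("events set on invalid pairs")

    @property
    def n_valid_pairs(self) -> np.ndarray:
        """Number of valid pairs per electrode."""
        return self.valid.sum(axis=0)

    @property
    def event_rate(self) -> float:
        """Events per valid electrode-pair slot over the whole series."""
        n = int(self.valid.sum())
        return float(self.events.sum()) / n if n else np.nan


@dataclass
class ActivityTimeSeries:
    """Binned cage activity with window labels.

    ``df`` is indexed by bin start and carries::

        events       summed activation events in the bin (all electrodes)
        valid_slots  valid electrode-pair slots in the bin
        activity     events / valid_slots, NaN where valid_slots == 0
        phase        'day' / 'night' (if a light schedule was supplied)
        week         cage-change-cycle index (-1 before the first anchor)
        cycle_day    weekday-of-cycle, 0 = calendar day of the cage-change
        day          calendar day (normalised timestamp)

    Bins with zero valid slots are present but marked missing (NaN activity),
    never silently zero.
    """

    cage_id: str
    bin_width: pd.Timedelta
    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def activity(self) -> np.ndarray:
        return self.df["activity"].to_numpy()

    @property
    def bin_start(self) -> pd.DatetimeIndex:
        return self.df.index

    def label(
        self,
        schedule: LightSchedule | None = None,
        calendar: InterventionCalendar | None = None,
    ) -> "ActivityTimeSeries":
        """Attach day/night, week and weekday-of-cycle labels in place."""
        idx = self.df.index
        if schedule is not None:
            self.df["phase"] = schedule.phase_of(idx)
        if calendar is not None:
            week, cycle_day = calendar.label(idx)
            self.df["week"] = week
            self.df["cycle_day"] = cycle_day
        self.df["day"] = idx.normalize()
        return self

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> "ActivityTimeSeries":
        return replace(self, df=self.df.loc[start:end].iloc[:-1]
                       if end in self.df.index else self.df.loc[start:end])

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per bin with cage metadata columns."""
        out = self.df.reset_index(names="bin_start")
        out.insert(0, "cage_id", self.cage_id)
        out.insert(2, "bin_width_s",
                   self.bin_width / pd.Timedelta(seconds=1))
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ActivityTimeSeries":
        """Inverse of :meth:`to_frame` (single cage)."""
        cage_ids = frame["cage_id"].unique()
        if len(cage_ids) != 1:
            raise ValidationError("expected a single cage_id")
        bw = pd.Timedelta(seconds=float(frame["bin_width_s"].iloc[0]))
        df = frame.drop(columns=["cage_id", "bin_width_s"]).copy()
        df["bin_start"] = pd.to_datetime(df["bin_start"], utc=True)
        df = df.set_index("bin_start")
        if "day" in df.columns:
            df["day"] = pd.to_datetime(df["day"], utc=True)
        return cls(cage_id=str(cage_ids[0]), bin_width=bw, df=df)


@dataclass
class FloorAreaSeries:
    """One binned activity series per floor area (rows of three electrodes)."""

    areas: dict[str, ActivityTimeSeries]

    def __iter__(self):
        return iter(self.areas.items())

    def global_series(self) -> ActivityTimeSeries:
        """Slot-weighted recombination of the four areas.

        Equals the all-electrode series exactly (same events, same slots).
        """
        first = next(iter(self.areas.values()))
        events = sum(a.df["events"] for a in self.areas.values())
        slots = sum(a.df["valid_slots"] for a in self.areas.values())
        df = first.df.copy()
        df["events"] = events
        df["valid_slots"] = slots
        with np.errstate(invalid="ignore", divide="ignore"):
            df["activity"] = np.where(slots > 0, events / slots, np.nan)
        return ActivityTimeSeries(first.cage_id, first.bin_width, df)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def estimate_noise_threshold(
    signal: SignalTable,
    k: float = 4.0,
    quiescent_window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    schedule: LightSchedule | None = None,
    max_pair_gap: pd.Timedelta | None = None,
    per_electrode: bool = True,
) -> np.ndarray:
    """Per-electrode threshold theta_e = k x robust scale of first differences.

    The robust scale is MAD x 1.4826 of the signed first differences in a
    quiescent window, so ``k`` is expressed in units of the standard
    deviation of the *differenced* noise.  The default window is the mid-day
    rest block (4-8 h after lights-on) when a schedule is supplied, otherwise
    the whole recording.  Requires at least 100 valid pairs per electrode.
    """
    diffs, pair_times, valid = _pair_differences(signal, max_pair_gap)
    mask = np.ones(len(diffs), dtype=bool)
    if quiescent_window is not None:
        lo, hi = quiescent_window
        mask &= (pair_times >= lo) & (pair_times < hi)
    elif schedule is not None:
        tod = pair_times - pair_times.normalize()
        on = pd.Timedelta(hours=schedule.lights_on.hour,
                          minutes=schedule.lights_on.minute)
        rest_lo = (on + pd.Timedelta(hours=4)) % pd.Timedelta(hours=24)
        rest_hi = (on + pd.Timedelta(hours=8)) % pd.Timedelta(hours=24)
        if rest_lo <= rest_hi:
            mask &= np.asarray((tod >= rest_lo) & (tod < rest_hi))
        else:  # rest block wraps midnight
            mask &= np.asarray((tod >= rest_lo) | (tod < rest_hi))
    theta = np.empty(N_ELECTRODES)
    for e in range(N_ELECTRODES):
        d = diffs[mask & valid[:, e], e]
        if d.size < 100:
            raise ValidationError(
                f"electrode e{e + 1:02d}: only {d.size} valid pairs in the "
                "quiescent window (need >= 100)")
        med = np.median(d)
        theta[e] = k * MAD_SCALE * np.median(np.abs(d - med))
    if not per_electrode:
        theta[:] = np.median(theta)
    return theta


def _pair_differences(
    signal: SignalTable, max_pair_gap: pd.Timedelta | None
) -> tuple[np.ndarray, pd.DatetimeIndex, np.ndarray]:
    """(signed differences, pair times, finite-validity) for retained pairs."""
    if max_pair_gap is None:
        max_pair_gap = 2 * signal.sampling_period
    if len(signal) < 2:
        empty = np.empty((0, N_ELECTRODES))
        return empty, signal.time[:0], empty.astype(bool)
    gaps_ok = np.diff(signal.time.asi8) <= max_pair_gap.value
    later = signal.values[1:][gaps_ok]
    earlier = signal.values[:-1][gaps_ok]
    diffs = later - earlier
    valid = np.isfinite(later) & np.isfinite(earlier)
    return diffs, signal.time[1:][gaps_ok], valid


def detect_activations(
    signal: SignalTable,
    threshold: DetectionPolicy | float | np.ndarray = None,
    max_pair_gap: pd.Timedelta | None = None,
    schedule: LightSchedule | None = None,
) -> ActivationSeries:
    """Threshold the absolute first differences into activation events.

    ``threshold`` may be a fixed scalar (sensor units), a per-electrode
    array, or a :class:`DetectionPolicy`; the default policy estimates a
    per-electrode threshold as 4 x the robust scale of the differenced noise
    (:func:`estimate_noise_threshold`).

    event(e, t) = [ |c_e(t) - c_e(t-1)| > theta_e ] on valid pairs only.
    """
    if threshold is None:
        threshold = DetectionPolicy()
    if isinstance(threshold, DetectionPolicy):
        if max_pair_gap is None:
            max_pair_gap = threshold.max_pair_gap
        if threshold.policy == "fixed":
            theta = np.full(N_ELECTRODES, float(threshold.fixed_value))
        else:
            theta = estimate_noise_threshold(
                signal, k=threshold.k, schedule=schedule,
                max_pair_gap=max_pair_gap,
                per_electrode=threshold.per_electrode)
    else:
        theta = np.broadcast_to(
            np.asarray(threshold, dtype=float), (N_ELECTRODES,)).copy()

    diffs, pair_times, valid = _pair_differences(signal, max_pair_gap)
    if valid.size == 0 or not valid.any():
        warnings.warn(f"cage {signal.cage_id}: no valid sample pairs")
    with np.errstate(invalid="ignore"):
        events = valid & (np.abs(diffs) > theta[None, :])
    return ActivationSeries(
        cage_id=signal.cage_id,
        pair_times=pair_times,
        events=events,
        valid=valid,
        threshold_used=theta,
    )


# ---------------------------------------------------------------------------
# binning and grouping
# ---------------------------------------------------------------------------

def _bin_counts(
    acts: ActivationSeries,
    bin_width: pd.Timedelta,
    electrodes: np.ndarray | None = None,
) -> tuple[pd.DatetimeIndex, np.ndarray, np.ndarray]:
    """(bin starts, event counts, valid-slot counts) on a contiguous bin grid.

    A pair belongs to the bin containing its later sample.
    """
    if len(acts.pair_times) == 0:
        return acts.pair_times[:0], np.zeros(0), np.zeros(0)
    bw_ns = bin_width.value
    t = acts.pair_times.asi8
    t0 = (t[0] // bw_ns) * bw_ns
    codes = (t - t0) // bw_ns
    n_bins = int(codes[-1]) + 1
    cols = slice(None) if electrodes is None else electrodes
    ev = acts.events[:, cols].sum(axis=1).astype(float)
    va = acts.valid[:, cols].sum(axis=1).astype(float)
    events = np.bincount(codes, weights=ev, minlength=n_bins)
    slots = np.bincount(codes, weights=va, minlength=n_bins)
    starts = pd.DatetimeIndex(t0 + np.arange(n_bins) * bw_ns,
                              tz=acts.pair_times.tz)
    return starts, events, slots


def bin_activity(
    acts: ActivationSeries,
    bin_width: pd.Timedelta = pd.Timedelta(minutes=1),
    schedule: LightSchedule | None = None,
    calendar: InterventionCalendar | None = None,
    electrodes: list[int] | None = None,
) -> ActivityTimeSeries:
    """Bin events into fractional activity over all (or selected) electrodes.

    Per-bin activity = events / valid electrode-pair slots, pooled across
    electrodes; with all slots valid this equals the mean over electrodes of
    per-electrode activity.  ``electrodes`` selects a subset by 1-based
    index (used for floor areas).
    """
    sel = None if electrodes is None else np.asarray(electrodes) - 1
    starts, events, slots = _bin_counts(acts, bin_width, sel)
    with np.errstate(invalid="ignore", divide="ignore"):
        activity = np.where(slots > 0, events / np.maximum(slots, 1), np.nan)
    df = pd.DataFrame(
        {"events": events, "valid_slots": slots, "activity": activity},
        index=pd.Index(starts, name="bin_start"),
    )
    out = ActivityTimeSeries(cage_id=acts.cage_id, bin_width=bin_width, df=df)
    return out.label(schedule, calendar)


def spatial_group(
    acts: ActivationSeries,
    layout: ElectrodeLayout | None = None,
    bin_width: pd.Timedelta = pd.Timedelta(minutes=1),
    schedule: LightSchedule | None = None,
    calendar: InterventionCalendar | None = None,
) -> FloorAreaSeries:
    """Bin activity separately for the four floor areas (rows of 3 electrodes).

    The slot-weighted mean of the four area series reconstructs the global
    all-electrode series exactly.
    """
    layout = layout or ElectrodeLayout.default()
    areas = {
        label: bin_activity(acts, bin_width, schedule, calendar,
                            electrodes=list(elec))
        for label, elec in layout.floor_areas.items()
    }
    return FloorAreaSeries(areas=areas)


# ---------------------------------------------------------------------------
# normalisation and fractions
# ---------------------------------------------------------------------------

def normalize_activity(
    series: ActivityTimeSeries,
    window: str = "cycle",
) -> ActivityTimeSeries:
    """Divide each bin by the mean activity of its reference window.

    ``window='cycle'`` groups bins by cage-change cycle (the ``week`` label);
    ``window='all'`` uses one window for the whole series.  The mean is over
    non-missing bins, so each window of the output has unit mean.  Windows
    with zero mean are marked non-normalisable (bins set missing).
    """
    df = series.df.copy()
    if window == "cycle":
        if "week" not in df.columns:
            raise ValidationError("series has no cycle labels; "
                                  "bin with a calendar first")
        groups = df["week"].to_numpy()
    elif window == "all":
        groups = np.zeros(len(df), dtype=int)
    else:
        raise ValidationError(f"unknown window {window!r}")
    act = df["activity"].to_numpy(dtype=float, copy=True)
    for g in np.unique(groups):
        m = groups == g
        mean = np.nanmean(act[m]) if np.isfinite(act[m]).any() else np.nan
        if not np.isfinite(mean) or mean <= 0:
            act[m] = np.nan
        else:
            act[m] = act[m] / mean
    df["activity"] = act
    return ActivityTimeSeries(series.cage_id, series.bin_width, df)


def activity_fraction(
    series: ActivityTimeSeries | FloorAreaSeries,
    partition: str = "phase",
    schedule: LightSchedule | None = None,
) -> pd.DataFrame:
    """Percentage of total activity allocated to each part of a partition.

    ``partition='phase'`` splits each 24 h period into day/night and returns
    one row per period with columns ``day`` and ``night`` summing to 100%
    (periods with no events are undefined -> NaN).  When a ``schedule`` is
    given, periods are anchored at lights-on so each holds one complete
    light phase and one complete dark phase; otherwise calendar days are
    used.  ``partition='area'`` expects a :class:`FloorAreaSeries` and
    splits by floor area.
    """
    if partition == "phase":
        if not isinstance(series, ActivityTimeSeries):
            raise ValidationError("phase fractions need a single series")
        df = series.df
        if "phase" not in df.columns:
            raise ValidationError("series has no phase labels")
        if schedule is not None:
            on = pd.Timedelta(hours=schedule.lights_on.hour,
                              minutes=schedule.lights_on.minute)
            period = (df.index - on).normalize() + on
        else:
            period = df["day"]
        tot = df.groupby([pd.Index(period, name="period"), df["phase"]],
                         observed=True)["events"].sum()
        wide = tot.unstack("phase").reindex(columns=["day", "night"],
                                            fill_value=0.0)
        totals = wide.sum(axis=1)
        frac = wide.div(totals, axis=0) * 100.0
        frac[totals == 0] = np.nan
        return frac
    if partition == "area":
        if not isinstance(series, FloorAreaSeries):
            raise ValidationError("area fractions need a FloorAreaSeries")
        events = {label: a.df["events"].sum() for label, a in series}
        total = float(sum(events.values()))
        return pd.DataFrame(
            {label: [100.0 * v / total if total else np.nan]
             for label, v in events.items()})
    raise ValidationError(f"unknown partition {partition!r}")
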
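"""Descriptive surfaces: heat maps, actigrams, longitudinal tables.

These operations export the analysis-ready matrices behind the usual
home-cage figures — a day x time-of-day activity heat map, an actigram with
the night-phase trace superimposed on the day-phase trace, and a tidy
longitudinal table (one row per cage, cage-change cycle, weekday-of-cycle
and light phase) suitable for external rank-based longitudinal statistics.
Plotting is a thin convenience over the exported matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import ActivityTimeSeries, normalize_activity
from .signal_io import CageInfo, ValidationError

__all__ = [
    "ActigramData",
    "heatmap_matrix",
    "actigram",
    "build_longitudinal_table",
    "cycle_day_permutation_p",
    "plot_heatmap",
    "plot_actigram",
]


def heatmap_matrix(
    series: ActivityTimeSeries,
    days: tuple[int, int] | None = None,
    col_minutes: int = 1,
    schedule=None,
) -> pd.DataFrame:
    """Day x time-of-day activity matrix.

    Rows are 24 h periods — anchored at lights-on when a ``schedule`` is
    given (day break at column 0, matching the usual heat-map convention),
    calendar days otherwise — optionally sliced to ``days=(first, last)``
    0-based offsets.  Columns are minute-of-day bins aggregated to
    ``col_minutes``; values are mean activity, NaN where bins are missing.
    """
    if len(series) == 0:
        raise ValidationError("empty series")
    idx = series.bin_start
    if schedule is not None:
        on = pd.Timedelta(hours=schedule.lights_on.hour,
                          minutes=schedule.lights_on.minute)
        day = (idx - on).normalize() + on
    else:
        day = idx.normalize()
    minute_of_day = ((idx - day) / pd.Timedelta(minutes=1)).astype(int)
    col = (minute_of_day // col_minutes) * col_minutes
    frame = pd.DataFrame({
        "day": day, "col": col, "activity": series.activity})
    mat = frame.pivot_table(index="day", columns="col", values="activity",
                            aggfunc="mean", dropna=False)
    if days is not None:
        mat = mat.iloc[days[0]:days[1] + 1]
    return mat


@dataclass
class ActigramData:
    """Hourly day-phase and night-phase activity traces.

    ``df`` is indexed by hour-of-phase (0-11 for a 12/12 schedule), hours
    counted from lights-on for the day trace and from lights-off for the
    night trace (a 12 h phase shift), with mean and SD of the per-minute
    activity in each hourly bin.
    """

    df: pd.DataFrame

    @property
    def day_mean(self) -> np.ndarray:
        return self.df["day_mean"].to_numpy()

    @property
    def night_mean(self) -> np.ndarray:
        return self.df["night_mean"].to_numpy()


def actigram(
    series: ActivityTimeSeries,
    schedule,
    weeks: list[int] | None = None,
) -> ActigramData:
    """Hourly means/SDs of per-minute activity, by phase-anchored hour.

    The day trace is binned from lights-on, the night trace from lights-off;
    ``weeks`` optionally restricts to the given cage-change-cycle indices.
    """
    df = series.df
    if "phase" not in df.columns:
        raise ValidationError("series has no phase labels")
    if weeks is not None:
        if "week" not in df.columns:
            raise ValidationError("series has no cycle labels")
        df = df[df["week"].isin(weeks)]
    idx = df.index
    tod = idx - idx.normalize()
    on = pd.Timedelta(hours=schedule.lights_on.hour,
                      minutes=schedule.lights_on.minute)
    off = pd.Timedelta(hours=schedule.lights_off.hour,
                       minutes=schedule.lights_off.minute)
    anchor = np.where(df["phase"].to_numpy() == "day",
                      on.value, off.value)
    hour = ((tod.asi8 - anchor) // 3_600_000_000_000) % 24
    tmp = pd.DataFrame({"phase": df["phase"].to_numpy(), "hour": hour,
                        "activity": df["activity"].to_numpy()})
    g = tmp.groupby(["phase", "hour"], observed=True)["activity"]
    stats = g.agg(["mean", "std"]).unstack("phase")
    n_hours = int(max(schedule.day_length, schedule.night_length)
                  / pd.Timedelta(hours=1))
    out = pd.DataFrame(index=pd.RangeIndex(n_hours, name="hour"))
    for phase in ("day", "night"):
        out[f"{phase}_mean"] = stats["mean"].get(
            phase, pd.Series(dtype=float)).reindex(out.index)
        out[f"{phase}_sd"] = stats["std"].get(
            phase, pd.Series(dtype=float)).reindex(out.index)
    return ActigramData(df=out)


def build_longitudinal_table(
    series: ActivityTimeSeries,
    cage: CageInfo | None = None,
    normalization: str = "cycle",
) -> pd.DataFrame:
    """Tidy longitudinal table: one row per (week, cycle_day, phase).

    Carries the slot-weighted mean activity, the summed valid-slot weight
    and the mean cycle-normalised activity of each cell; cage metadata
    columns (site, sex) come from ``cage``.  Rows cover observed
    combinations only; cells belonging to an incomplete trailing cycle are
    flagged in ``complete_cycle``.
    """
    df = series.df
    for col in ("phase", "week", "cycle_day"):
        if col not in df.columns:
            raise ValidationError(f"series lacks the {col!r} label")
    norm = normalize_activity(series, window=normalization)
    work = df.assign(normalized=norm.df["activity"])
    work = work[work["week"] >= 0]
    if work.empty:
        raise ValidationError("calendar defines no complete cycle")
    last_week = int(work["week"].max())
    full_days = int(work.groupby("week")["cycle_day"].nunique().iloc[:-1].max()
                    ) if last_week > 0 else -1

    def _agg(g: pd.DataFrame) -> pd.Series:
        slots = g["valid_slots"].sum()
        events = g["events"].sum()
        return pd.Series({
            "activity": events / slots if slots > 0 else np.nan,
            "valid_slots": slots,
            "normalized": g["normalized"].mean(),
            "n_bins": len(g),
        })

    grouped = (work.groupby(["week", "cycle_day", "phase"], observed=True)
               .apply(_agg, include_groups=False).reset_index())
    grouped["complete_cycle"] = True
    if last_week > 0:
        trailing_days = work.loc[work["week"] == last_week,
                                 "cycle_day"].nunique()
        if trailing_days < full_days:
            grouped.loc[grouped["week"] == last_week, "complete_cycle"] = False
    grouped.insert(0, "cage_id", series.cage_id)
    if cage is not None:
        grouped.insert(1, "site", cage.site)
        grouped.insert(2, "sex", cage.sex)
    return grouped


def cycle_day_permutation_p(
    values: np.ndarray,
    day_labels: np.ndarray,
    n_perm: int = 500,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for a weekday-of-cycle effect.

    The statistic is the variance of the cycle-day group means of the
    per-day summary ``values``; the null distribution permutes values across
    days.  Used as the negative control: with interventions disabled, cycle
    days are exchangeable and p is uniform.
    """
    rng = rng or np.random.default_rng()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(day_labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        return 1.0

    def stat(v: np.ndarray) -> float:
        means = pd.Series(v).groupby(labels).mean()
        return float(np.var(means.to_numpy()))

    observed = stat(values)
    hits = 0
    for _ in range(n_perm):
        if stat(rng.permutation(values)) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# thin plots
# ---------------------------------------------------------------------------

def plot_heatmap(mat: pd.DataFrame, path: str) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 0.25 * len(mat) + 2))
    im = ax.imshow(mat.to_numpy(), aspect="auto", interpolation="nearest",
                   cmap="viridis")
    ax.set_xlabel("minute of day")
    ax.set_ylabel("day")
    fig.colorbar(im, ax=ax, label="activity")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_actigram(data: ActigramData, path: str) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    h = data.df.index.to_numpy()
    for phase, color in (("day", "tab:blue"), ("night", "tab:red")):
        mean = data.df[f"{phase}_mean"]
        sd = data.df[f"{phase}_sd"]
        ax.plot(h, mean, color=color, label=phase)
        ax.fill_between(h, mean - sd, mean + sd, color=color, alpha=0.2)
    ax.set_xlabel("hour of phase")
    ax.set_ylabel("activity")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
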
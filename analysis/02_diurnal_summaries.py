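#!/usr/bin/env python
"""Diurnal structure of the simulated cohort: fractions, actigram, heat map.

Reads the minute activity tables produced by 01_simulate_cohort.py and
exports the descriptive surfaces:

  results/day_night_fractions.csv   per-cage, per-24h-period day/night %
  results/actigram_KI-like.csv      hourly day/night traces (KI-like cage)
  results/heatmap_KI-like.csv       day x time-of-day matrix, 10-min columns
"""

import sys
from pathlib import Path

import pandas as pd

from cagepulse import (
    ActivityTimeSeries,
    LightSchedule,
    activity_fraction,
    actigram,
    heatmap_matrix,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SCENARIOS = ["CNR-like", "JAX-like", "KI-like", "male-KI-like"]


def load(name: str) -> ActivityTimeSeries:
    path = SCRATCH / f"activity_{name}.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing - run 01_simulate_cohort.py first")
    return ActivityTimeSeries.from_frame(pd.read_csv(path))


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    schedule = LightSchedule()
    frames = []
    for name in SCENARIOS:
        series = load(name)
        frac = activity_fraction(series, schedule=schedule).dropna()
        frac = frac.reset_index()
        frac.insert(0, "scenario", name)
        frames.append(frac)
        print(f"{name}: night fraction {frac['night'].mean():.1f}% "
              f"(day {frac['day'].mean():.1f}%) across {len(frac)} days")
    fractions = pd.concat(frames, ignore_index=True)
    fractions.to_csv(RESULTS / "day_night_fractions.csv", index=False)

    ki = load("KI-like")
    acti = actigram(ki, schedule)
    acti.df.to_csv(RESULTS / "actigram_KI-like.csv")
    burst_hour = int(acti.df["day_mean"].idxmax())
    print(f"KI-like actigram: day-phase activity peaks in hour {burst_hour} "
          "after lights-on (the post-lights-on burst), night trace exceeds "
          f"the day trace in {int((acti.df['night_mean'] > acti.df['day_mean']).sum())}"
          f"/{len(acti.df)} hourly bins")

    mat = heatmap_matrix(ki, col_minutes=10, schedule=schedule)
    mat.to_csv(RESULTS / "heatmap_KI-like.csv")
    night_cols = [c for c in mat.columns if c >= 720]
    day_cols = [c for c in mat.columns if c < 720]
    print(f"KI-like heat map: {mat.shape[0]} days x {mat.shape[1]} columns; "
          f"night-column mean {mat[night_cols].mean().mean():.4f} vs "
          f"day-column mean {mat[day_cols].mean().mean():.4f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
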
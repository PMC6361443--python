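"""Raw-signal and study-configuration I/O.

On-disk dialects
----------------
Raw capacitance tables are CSV with header ``cage_id,timestamp,e01,...,e12``,
one row per 250 ms sample.  Timestamps are ISO-8601 with millisecond
resolution and an explicit UTC offset; values are dimensionless capacitance
sensor units (no physical calibration exists for these boards).  An optional
HDF5 container with the same logical schema is provided for long recordings.

Study configuration is a flat YAML document: cage metadata, the light
schedule, the intervention calendar (cage-changes, weighings) and the
activation-detection policy.  Defaults applied while loading are recorded in
a provenance block on the returned :class:`StudyConfig`.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "SignalTable",
    "ElectrodeLayout",
    "LightSchedule",
    "InterventionCalendar",
    "CageInfo",
    "DetectionPolicy",
    "StudyConfig",
    "read_signal",
    "write_signal",
    "read_signal_hdf5",
    "write_signal_hdf5",
    "load_study_config",
]

N_ELECTRODES = 12
ELECTRODE_COLUMNS = [f"e{i:02d}" for i in range(1, N_ELECTRODES + 1)]
SAMPLING_PERIOD = pd.Timedelta(milliseconds=250)

#: Floor-area labels, front of the cage first.
FLOOR_AREA_LABELS = ("front", "middle-front", "middle-rear", "rear")


class SchemaError(ValueError):
    """A file does not conform to the declared on-disk dialect."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SignalTable:
    """Timestamped raw capacitance readings for the 12 electrodes of one cage.

    Attributes
    ----------
    cage_id
        Opaque cage identifier.
    time
        Strictly increasing tz-aware instants, nominal spacing 250 ms.
    values
        ``(n_samples, 12)`` float array of capacitance readings in sensor
        units, columns ordered by electrode index 1..12.
    sampling_period
        Nominal sampling interval (default 250 ms).
    n_rejected_rows
        Rows dropped at parse time because their timestamp was unreadable.
    """

    cage_id: str
    time: pd.DatetimeIndex
    values: np.ndarray
    sampling_period: pd.Timedelta = SAMPLING_PERIOD
    n_rejected_rows: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_ELECTRODES:
            raise ValidationError(
                f"expected {N_ELECTRODES} electrode columns, got shape "
                f"{self.values.shape}"
            )
        if len(self.time) != len(self.values):
            raise ValidationError("timestamps and values disagree in length")
        if len(self.time) > 1:
            deltas = np.diff(self.time.asi8)
            bad = np.nonzero(deltas <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"timestamps not strictly increasing at row {bad[0] + 1}"
                )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def nonfinite_rows(self) -> np.ndarray:
        """Indices of rows containing at least one non-finite reading.

        Such rows are flagged rather than dropped; pair differencing
        invalidates the pairs they touch (see :mod:`cagepulse.activity`).
        """
        return np.nonzero(~np.isfinite(self.values).all(axis=1))[0]

    def equals(self, other: "SignalTable", rtol: float = 1e-6) -> bool:
        return (
            self.cage_id == other.cage_id
            and len(self) == len(other)
            and bool(self.time.equals(other.time))
            and np.allclose(self.values, other.values, rtol=rtol, equal_nan=True)
        )


@dataclass(frozen=True)
class ElectrodeLayout:
    """Geometry of the 4 x 3 electrode grid under the cage floor.

    ``grid`` maps electrode index (1..12) to ``(row, column)`` with row 0 the
    front of the cage; ``floor_areas`` maps the four area labels (front,
    middle-front, middle-rear, rear) to the three electrode indices in the
    corresponding row.
    """

    grid: dict[int, tuple[int, int]]
    floor_areas: dict[str, tuple[int, int, int]]

    def __post_init__(self) -> None:
        all_elec = sorted(e for area in self.floor_areas.values() for e in area)
        if all_elec != list(range(1, N_ELECTRODES + 1)):
            raise ValidationError("floor areas must partition electrodes 1..12")
        if any(len(area) != 3 for area in self.floor_areas.values()):
            raise ValidationError("each floor area must hold exactly 3 electrodes")

    @classmethod
    def default(cls) -> "ElectrodeLayout":
        grid = {
            e: ((e - 1) // 3, (e - 1) % 3) for e in range(1, N_ELECTRODES + 1)
        }
        areas = {
            label: tuple(range(3 * i + 1, 3 * i + 4))
            for i, label in enumerate(FLOOR_AREA_LABELS)
        }
        return cls(grid=grid, floor_areas=areas)


@dataclass(frozen=True)
class LightSchedule:
    """Instant (step) light transitions repeating every 24 h."""

    lights_on: dt.time = dt.time(6, 0)
    lights_off: dt.time = dt.time(18, 0)

    def __post_init__(self) -> None:
        if self.lights_on == self.lights_off:
            raise ValidationError("lights-on and lights-off must differ")

    @property
    def day_length(self) -> pd.Timedelta:
        on = _time_to_td(self.lights_on)
        off = _time_to_td(self.lights_off)
        return (off - on) % pd.Timedelta(hours=24)

    @property
    def night_length(self) -> pd.Timedelta:
        return pd.Timedelta(hours=24) - self.day_length

    def phase_of(self, times: pd.DatetimeIndex) -> np.ndarray:
        """Label each instant ``'day'`` (lights on) or ``'night'``."""
        tod = times - times.normalize()
        on = _time_to_td(self.lights_on)
        off = _time_to_td(self.lights_off)
        if on < off:
            is_day = (tod >= on) & (tod < off)
        else:
            is_day = (tod >= on) | (tod < off)
        return np.where(is_day, "day", "night")

    def transitions(
        self, start: pd.Timestamp, end: pd.Timestamp, which: str = "lights_off"
    ) -> pd.DatetimeIndex:
        """All lights-on or lights-off instants within ``[start, end)``."""
        clock = self.lights_off if which == "lights_off" else self.lights_on
        first = start.normalize() + _time_to_td(clock)
        while first < start:
            first += pd.Timedelta(days=1)
        out = []
        t = first
        while t < end:
            out.append(t)
            t += pd.Timedelta(days=1)
        return pd.DatetimeIndex(out, tz=start.tz)


@dataclass
class InterventionCalendar:
    """Time-sorted husbandry events; cycles are bounded by the anchor type."""

    events: list[tuple[str, pd.Timestamp]] = field(default_factory=list)
    cycle_anchor: str = "cage_change"

    def __post_init__(self) -> None:
        self.events = [(str(k), pd.Timestamp(t)) for k, t in self.events]
        times = [t for _, t in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            self.events.sort(key=lambda kv: kv[1])

    @property
    def anchors(self) -> pd.DatetimeIndex:
        times = [t for k, t in self.events if k == self.cycle_anchor]
        return pd.DatetimeIndex(times)

    def cycles(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        """Complete cycles between consecutive anchor events."""
        a = self.anchors
        return [(a[i], a[i + 1]) for i in range(len(a) - 1)]

    def events_of_type(self, event_type: str) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([t for k, t in self.events if k == event_type])

    def label(
        self, times: pd.DatetimeIndex
    ) -> tuple[np.ndarray, np.ndarray]:
        """(week index, weekday-of-cycle) labels for each instant.

        Week ``i`` starts at anchor ``i``; day 0 is the calendar day of the
        anchor (intervention day).  Instants before the first anchor get week
        ``-1`` and day ``-1``.
        """
        week = np.full(len(times), -1, dtype=int)
        cycle_day = np.full(len(times), -1, dtype=int)
        anchors = self.anchors
        if len(anchors) == 0 or len(times) == 0:
            return week, cycle_day
        idx = np.searchsorted(anchors.asi8, times.asi8, side="right") - 1
        inside = idx >= 0
        week[inside] = idx[inside]
        anchor_days = anchors.normalize().asi8
        day_ns = 86_400_000_000_000
        t_days = times.normalize().asi8
        cycle_day[inside] = (
            (t_days[inside] - anchor_days[idx[inside]]) // day_ns
        )
        return week, cycle_day


@dataclass(frozen=True)
class CageInfo:
    cage_id: str
    site: str = ""
    sex: str = ""
    n_animals: int = 5

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ValidationError("n_animals must be >= 0")


@dataclass(frozen=True)
class DetectionPolicy:
    """How the activation threshold is chosen.

    ``policy='fixed'`` uses ``fixed_value`` directly (sensor units, applied
    to the absolute first difference).  ``policy='mad'`` sets a per-electrode
    threshold of ``k`` times the robust scale (MAD x 1.4826) of the first
    differences in a quiescent window.
    """

    policy: str = "mad"
    k: float = 4.0
    fixed_value: float | None = None
    per_electrode: bool = True
    max_pair_gap: pd.Timedelta = pd.Timedelta(milliseconds=500)

    def __post_init__(self) -> None:
        if self.policy not in ("mad", "fixed"):
            raise ValidationError(f"unknown threshold policy {self.policy!r}")
        if self.policy == "fixed" and self.fixed_value is None:
            raise ValidationError("fixed policy requires fixed_value")


@dataclass
class StudyConfig:
    cages: list[CageInfo]
    light_schedule: LightSchedule
    calendar: InterventionCalendar
    detection: DetectionPolicy = field(default_factory=DetectionPolicy)
    recording_start: pd.Timestamp | None = None
    recording_end: pd.Timestamp | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.cage_id for c in self.cages]
        if len(set(ids)) != len(ids):
            raise ValidationError("cage_id values must be unique")

    def cage(self, cage_id: str) -> CageInfo:
        for c in self.cages:
            if c.cage_id == cage_id:
                return c
        raise KeyError(cage_id)


def _time_to_td(t: dt.time) -> pd.Timedelta:
    return pd.Timedelta(hours=t.hour, minutes=t.minute, seconds=t.second)


# ---------------------------------------------------------------------------
# raw signal CSV dialect
# ---------------------------------------------------------------------------

def read_signal(path: str | Path) -> SignalTable:
    """Read a raw capacitance CSV into a validated :class:`SignalTable`.

    Rows whose timestamp cannot be parsed are rejected and counted in
    ``n_rejected_rows``; shuffled electrode columns are normalised to index
    order; a missing electrode column or non-monotonic timestamps are fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cage_id": str})
    missing = [c for c in ("cage_id", "timestamp", *ELECTRODE_COLUMNS)
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    stamps = pd.to_datetime(df["timestamp"], errors="coerce", utc=True,
                            format="ISO8601")
    rejected = int(stamps.isna().sum())
    if rejected:
        warnings.warn(f"{path.name}: rejected {rejected} row(s) with "
                      "unparseable timestamps")
        df = df.loc[stamps.notna()]
        stamps = stamps.loc[stamps.notna()]
    cage_ids = df["cage_id"].unique() if len(df) else np.array([], dtype=object)
    if len(cage_ids) > 1:
        raise SchemaError(f"{path.name}: more than one cage_id present")
    cage_id = str(cage_ids[0]) if len(cage_ids) else path.stem
    time = pd.DatetimeIndex(stamps)
    if len(time) > 1:
        deltas = np.diff(time.asi8)
        bad = np.nonzero(deltas <= 0)[0]
        if bad.size:
            raise SchemaError(
                f"{path.name}: non-monotonic timestamp at data row "
                f"{int(bad[0]) + 1}"
            )
    values = df[ELECTRODE_COLUMNS].to_numpy(dtype=float)
    return SignalTable(cage_id=cage_id, time=time, values=values,
                       n_rejected_rows=rejected)


def write_signal(table: SignalTable, path: str | Path) -> Path:
    """Write a :class:`SignalTable` in the raw-signal CSV dialect.

    Timestamps are ISO-8601 with milliseconds and a +00:00 offset; values are
    printed with 8 significant digits so that ``read_signal(write_signal(t))``
    round-trips within declared precision and re-writing is byte-stable.
    """
    path = Path(path)
    utc = table.time.tz_convert("UTC") if table.time.tz is not None else \
        table.time.tz_localize("UTC")
    stamps = utc.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3] + "+00:00"
    with open(path, "w", newline="") as fh:
        fh.write("cage_id,timestamp," + ",".join(ELECTRODE_COLUMNS) + "\n")
        for ts, row in zip(stamps, table.values):
            fields = ",".join(f"{v:.8g}" for v in row)
            fh.write(f"{table.cage_id},{ts},{fields}\n")
    return path


def write_signal_hdf5(table: SignalTable, path: str | Path) -> Path:
    """Same logical schema as the CSV dialect, in an HDF5 container."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["cage_id"] = table.cage_id
        f.attrs["sampling_period_ms"] = table.sampling_period / pd.Timedelta(
            milliseconds=1)
        f.create_dataset("time_ns", data=table.time.tz_convert("UTC").asi8)
        f.create_dataset("values", data=table.values)
    return path


def read_signal_hdf5(path: str | Path) -> SignalTable:
    import h5py

    with h5py.File(path, "r") as f:
        time = pd.DatetimeIndex(
            pd.to_datetime(f["time_ns"][:], utc=True))
        return SignalTable(
            cage_id=str(f.attrs["cage_id"]),
            time=time,
            values=f["values"][:],
            sampling_period=pd.Timedelta(
                milliseconds=float(f.attrs["sampling_period_ms"])),
        )


# ---------------------------------------------------------------------------
# study configuration (YAML)
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "lights_on": "06:00",
    "lights_off": "18:00",
    "cage_change_every_days": 7,
    "detection": {"policy": "mad", "k": 4.0, "max_pair_gap_ms": 500},
}


def load_study_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML study configuration.

    Defaults (12/12 light schedule, weekly cage-change spacing when a
    generator block is used, MAD x 4 detection) are applied where the
    document is silent and recorded in ``StudyConfig.provenance``.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    provenance: dict = {"source": str(path), "defaults_applied": []}

    def _get(key: str, default):
        if key in doc:
            return doc[key]
        provenance["defaults_applied"].append(key)
        return default

    schedule = LightSchedule(
        lights_on=_parse_clock(_get("lights_on", _DEFAULTS["lights_on"])),
        lights_off=_parse_clock(_get("lights_off", _DEFAULTS["lights_off"])),
    )
    if schedule.day_length != pd.Timedelta(hours=12):
        provenance["non_default_photoperiod"] = str(schedule.day_length)

    cages_doc = doc.get("cages", [])
    if not cages_doc and "cage_id" in doc:
        cages_doc = [{"cage_id": doc["cage_id"]}]
    cages = [
        CageInfo(
            cage_id=str(c["cage_id"]),
            site=str(c.get("site", "")),
            sex=str(c.get("sex", "")),
            n_animals=int(c.get("n_animals", 5)),
        )
        for c in cages_doc
    ]

    calendar = _parse_calendar(doc.get("calendar", {}), provenance)

    det_doc = dict(_DEFAULTS["detection"])
    det_doc.update(doc.get("detection", {}) or {})
    detection = DetectionPolicy(
        policy=det_doc.get("policy", "mad"),
        k=float(det_doc.get("k", 4.0)),
        fixed_value=det_doc.get("fixed_value"),
        per_electrode=bool(det_doc.get("per_electrode", True)),
        max_pair_gap=pd.Timedelta(milliseconds=det_doc.get(
            "max_pair_gap_ms", 500)),
    )

    start = doc.get("recording_start")
    end = doc.get("recording_end")
    start = pd.Timestamp(start) if start else None
    end = pd.Timestamp(end) if end else None
    if start is not None and start.tz is None:
        start = start.tz_localize("UTC")
    if end is not None and end.tz is None:
        end = end.tz_localize("UTC")
    if start is not None and end is not None:
        outside = [t for _, t in calendar.events if not (start <= t <= end)]
        if outside:
            warnings.warn(
                f"{len(outside)} calendar event(s) fall outside the "
                "recording range; retained")

    return StudyConfig(
        cages=cages,
        light_schedule=schedule,
        calendar=calendar,
        detection=detection,
        recording_start=start,
        recording_end=end,
        provenance=provenance,
    )


def save_study_config(config: StudyConfig, path: str | Path) -> Path:
    """Serialise a StudyConfig back to the YAML dialect."""
    doc = {
        "lights_on": config.light_schedule.lights_on.strftime("%H:%M"),
        "lights_off": config.light_schedule.lights_off.strftime("%H:%M"),
        "cages": [dataclasses.asdict(c) for c in config.cages],
        "calendar": {
            "events": [
                {"type": k, "time": t.isoformat()}
                for k, t in config.calendar.events
            ],
            "cycle_anchor": config.calendar.cycle_anchor,
        },
        "detection": {
            "policy": config.detection.policy,
            "k": config.detection.k,
            "fixed_value": config.detection.fixed_value,
            "per_electrode": config.detection.per_electrode,
            "max_pair_gap_ms": config.detection.max_pair_gap
            / pd.Timedelta(milliseconds=1),
        },
    }
    if config.recording_start is not None:
        doc["recording_start"] = config.recording_start.isoformat()
    if config.recording_end is not None:
        doc["recording_end"] = config.recording_end.isoformat()
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def _parse_clock(value) -> dt.time:
    if isinstance(value, dt.time):
        return value
    if isinstance(value, (int, float)):  # YAML may parse 06:00 as seconds
        total = int(value)
        return dt.time(total // 3600, (total % 3600) // 60)
    parts = str(value).split(":")
    if len(parts) < 2:
        raise ValidationError(f"cannot parse clock time {value!r}")
    return dt.time(int(parts[0]), int(parts[1]),
                   int(parts[2]) if len(parts) > 2 else 0)


def _parse_calendar(cal_doc: dict, provenance: dict) -> InterventionCalendar:
    events: list[tuple[str, pd.Timestamp]] = []
    for ev in cal_doc.get("events", []) or []:
        t = pd.Timestamp(ev["time"])
        if t.tz is None:
            t = t.tz_localize("UTC")
        events.append((str(ev.get("type", "other")), t))

    # generator block: regular cage-changes (and optional weighings)
    if "first_cage_change" in cal_doc:
        every = int(cal_doc.get("cage_change_every_days",
                                _DEFAULTS["cage_change_every_days"]))
        if "cage_change_every_days" not in cal_doc:
            provenance["defaults_applied"].append("cage_change_every_days")
        if "n_cage_changes" in cal_doc:
            n_anchors = int(cal_doc["n_cage_changes"])
        elif "n_cycles" in cal_doc:  # n complete cycles need n+1 anchors
            n_anchors = int(cal_doc["n_cycles"]) + 1
        else:
            n_anchors = 1
        first = pd.Timestamp(cal_doc["first_cage_change"])
        if first.tz is None:
            first = first.tz_localize("UTC")
        for i in range(n_anchors):
            events.append(("cage_change", first + pd.Timedelta(days=every * i)))
        if "weighing_offset_days" in cal_doc:
            off = int(cal_doc["weighing_offset_days"])
            for i in range(max(n_anchors - 1, 0)):
                events.append(
                    ("weighing",
                     first + pd.Timedelta(days=every * i + off)))
    return InterventionCalendar(
        events=events,
        cycle_anchor=str(cal_doc.get("cycle_anchor", "cage_change")),
    )
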
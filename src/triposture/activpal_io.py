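"""Readers for activPAL-style raw acceleration, events and sleep-diary tables.

Three comma-separated file kinds feed the pipeline:

* a raw triaxial acceleration table per monitor (torso, thigh, shin), one row
  per 20 Hz sample, axes stored as integer ADC counts;
* an "events" table from the thigh monitor giving the start and duration of
  each activity bout to the nearest 0.1 s;
* a sleep diary with one wake/sleep time pair per monitored day.

Two device dialects are supported: AP3 (8 bits/sample, ±2 g) and AP4
(10 bits/sample, ±4 g).  Counts are converted to g through a symmetric linear
map (midpoint count -> 0 g) whose coefficients live in the :class:`Dialect`
and can be overridden for non-default vendor exports.

All internal times are seconds since the shared recording start (the monitors
are synchronized to start at midnight of the first day); the calendar mapping
is kept in metadata (`AccelTrace.start`, `DiaryDay.date`).  Intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime, time, timedelta
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CountRangeError,
    DialectError,
    EmptyInputError,
    FormatError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Site",
    "DeviceVersion",
    "Dialect",
    "AccelTrace",
    "EventRecord",
    "DiaryDay",
    "counts_to_g",
    "g_to_counts",
    "read_accel",
    "read_events",
    "read_diary",
]


class Site(str, Enum):
    TORSO = "torso"
    THIGH = "thigh"
    SHIN = "shin"


class DeviceVersion(str, Enum):
    AP3 = "AP3"
    AP4 = "AP4"


# version -> (offset, scale, count_min, count_max); g = (count - offset)/scale
_DEFAULT_COUNT_MAPS: dict[DeviceVersion, tuple[float, float, int, int]] = {
    DeviceVersion.AP3: (127.0, 63.0, 0, 255),
    DeviceVersion.AP4: (512.0, 128.0, 0, 1023),
}

#: default activity-code map for the events file (vendor exports vary)
_DEFAULT_ACTIVITY_CODES: dict[int, str] = {0: "sedentary", 1: "upright", 2: "upright"}

ACTIVITY_SEDENTARY = "sedentary"
ACTIVITY_UPRIGHT = "upright"
ACTIVITY_OTHER = "other"


@dataclass
class Dialect:
    """Column names, activity codes and count-map coefficients of a vendor export."""

    time_column: str = "time"
    axis_columns: tuple[str, str, str] = ("x", "y", "z")
    event_time_column: str = "time"
    event_duration_column: str = "duration_s"
    event_code_column: str = "activity_code"
    activity_codes: Mapping[int, str] = field(
        default_factory=lambda: dict(_DEFAULT_ACTIVITY_CODES)
    )
    diary_columns: tuple[str, str, str] = ("date", "wake", "sleep")
    count_maps: Mapping[DeviceVersion, tuple[float, float, int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_COUNT_MAPS)
    )

    def code_for(self, activity: str) -> int:
        """First integer code that maps to *activity* (used by writers)."""
        for code, act in self.activity_codes.items():
            if act == activity:
                return int(code)
        raise DialectError(f"no activity code maps to {activity!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in (
            "time_column",
            "event_time_column",
            "event_duration_column",
            "event_code_column",
        ):
            if key in raw:
                kwargs[key] = str(raw[key])
        if "axis_columns" in raw:
            kwargs["axis_columns"] = tuple(raw["axis_columns"])
        if "diary_columns" in raw:
            kwargs["diary_columns"] = tuple(raw["diary_columns"])
        if "activity_codes" in raw:
            kwargs["activity_codes"] = {int(k): str(v) for k, v in raw["activity_codes"].items()}
        if "count_maps" in raw:
            maps = {}
            for ver, coeffs in raw["count_maps"].items():
                maps[DeviceVersion(ver)] = (
                    float(coeffs[0]),
                    float(coeffs[1]),
                    int(coeffs[2]),
                    int(coeffs[3]),
                )
            kwargs["count_maps"] = maps
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "time_column": self.time_column,
            "axis_columns": list(self.axis_columns),
            "event_time_column": self.event_time_column,
            "event_duration_column": self.event_duration_column,
            "event_code_column": self.event_code_column,
            "activity_codes": {int(k): v for k, v in self.activity_codes.items()},
            "diary_columns": list(self.diary_columns),
            "count_maps": {
                ver.value: list(coeffs) for ver, coeffs in self.count_maps.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _count_map(
    version: DeviceVersion, dialect: Dialect | None
) -> tuple[float, float, int, int]:
    maps = dialect.count_maps if dialect is not None else _DEFAULT_COUNT_MAPS
    return maps[DeviceVersion(version)]


def counts_to_g(raw, version: DeviceVersion, dialect: Dialect | None = None):
    """Convert integer ADC counts to acceleration in g.

    The map is linear and strictly increasing, and sends the count midpoint to
    0 g: AP3 ``g = (count - 127)/63``, AP4 ``g = (count - 512)/128``.
    Counts outside the version's range raise :class:`CountRangeError`.
    """
    offset, scale, lo, hi = _count_map(version, dialect)
    arr = np.asarray(raw)
    if np.any(arr < lo) or np.any(arr > hi):
        raise CountRangeError(
            f"count(s) outside [{lo}, {hi}] for device version {DeviceVersion(version).value}"
        )
    out = (arr.astype(np.float64) - offset) / scale
    return float(out) if np.isscalar(raw) else out


def g_to_counts(g, version: DeviceVersion, dialect: Dialect | None = None):
    """Inverse count map with round-to-nearest and range saturation (ADC model)."""
    offset, scale, lo, hi = _count_map(version, dialect)
    arr = np.asarray(g, dtype=np.float64)
    counts = np.clip(np.rint(arr * scale + offset), lo, hi).astype(np.int64)
    return int(counts) if np.isscalar(g) else counts


def g_range(version: DeviceVersion, dialect: Dialect | None = None) -> tuple[float, float]:
    """Representable g interval implied by the count map."""
    offset, scale, lo, hi = _count_map(version, dialect)
    return (lo - offset) / scale, (hi - offset) / scale


@dataclass
class AccelTrace:
    """One monitor's uniformly sampled triaxial acceleration in g.

    Sample ``i`` occurs at ``start + i / sample_rate``; sampling is uniform.
    """

    site: Site
    start: datetime
    samples: np.ndarray  # (n, 3) float64, g
    sample_rate: float = 20.0
    device_version: DeviceVersion = DeviceVersion.AP3

    def __post_init__(self) -> None:
        self.site = Site(self.site)
        self.device_version = DeviceVersion(self.device_version)
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise FormatError("samples must have shape (n, 3)")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("acceleration samples must be finite")
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be positive")
        glo, ghi = g_range(self.device_version)
        if self.samples.size and (
            self.samples.min() < glo - 1e-9 or self.samples.max() > ghi + 1e-9
        ):
            raise FormatError(
                f"acceleration outside the {self.device_version.value} device range "
                f"[{glo:.3f}, {ghi:.3f}] g"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def times_s(self) -> np.ndarray:
        """Sample times in seconds since ``start``."""
        return np.arange(self.n_samples, dtype=np.float64) / self.sample_rate


@dataclass(frozen=True)
class EventRecord:
    """One thigh-classified activity bout (0.1 s start/duration resolution)."""

    start_s: float  # seconds since recording start
    duration_s: float
    activity: str  # "sedentary" | "upright" | "other"

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class DiaryDay:
    """Self-reported wake and sleep times for one monitored day.

    A sleep time-of-day at or before the wake time means sleep onset falls
    after midnight (next calendar day).  The sleep interval of a row runs from
    its sleep time to the next row's wake time; only the waking window
    ``[wake, sleep)`` is analysed.
    """

    date: _date
    wake: time
    sleep: time

    def waking_interval(self, origin: datetime) -> tuple[float, float]:
        """Waking window as seconds since *origin* (recording start)."""
        w = datetime.combine(self.date, self.wake)
        s = datetime.combine(self.date, self.sleep)
        if self.sleep <= self.wake:  # sleep onset after midnight
            s += timedelta(days=1)
        return (w - origin).total_seconds(), (s - origin).total_seconds()


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DialectError(f"{path}: missing column(s) {missing}; present: {list(df.columns)}")


def _parse_times(series: pd.Series, path: str | Path) -> pd.DatetimeIndex:
    try:
        return pd.DatetimeIndex(pd.to_datetime(series, format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp ({exc})") from exc


def read_accel(
    path: str | Path,
    site: Site,
    version: DeviceVersion,
    dialect: Dialect | None = None,
    sample_rate: float = 20.0,
) -> AccelTrace:
    """Read a raw triaxial acceleration CSV into an :class:`AccelTrace` in g.

    Axis columns hold integer ADC counts and are converted via
    :func:`counts_to_g`.  Rows must be time-ordered and uniformly spaced at
    ``sample_rate``.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no samples")
    _require_columns(df, (dialect.time_column, *dialect.axis_columns), path)

    counts = np.empty((len(df), 3), dtype=np.float64)
    for j, col in enumerate(dialect.axis_columns):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            # +2: 1-based data rows after the header line
            raise FormatError(f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}")
        counts[:, j] = vals

    times = _parse_times(df[dialect.time_column], path)
    dt_ns = np.diff(times.asi8)
    if dt_ns.size and dt_ns.min() <= 0:
        raise FormatError(f"{path}: timestamps are not strictly increasing")
    expected_ns = 1e9 / sample_rate
    if dt_ns.size and np.abs(dt_ns - expected_ns).max() > 1e5:  # 0.1 ms slack
        raise FormatError(
            f"{path}: sample spacing inconsistent with {sample_rate} samples/s"
        )

    g = counts_to_g(counts, version, dialect)
    return AccelTrace(
        site=Site(site),
        start=times[0].to_pydatetime(),
        samples=g,
        sample_rate=sample_rate,
        device_version=DeviceVersion(version),
    )


def read_events(
    path: str | Path,
    dialect: Dialect | None = None,
    origin: datetime | None = None,
) -> list[EventRecord]:
    """Read the thigh events CSV into time-ordered, non-overlapping records.

    *origin* fixes the zero of the internal clock; by default it is midnight
    of the first event's calendar day (the shared recording start).  Unknown
    activity codes map to ``"other"`` with a logged warning.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no events")
    cols = (
        dialect.event_time_column,
        dialect.event_duration_column,
        dialect.event_code_column,
    )
    _require_columns(df, cols, path)

    times = _parse_times(df[dialect.event_time_column], path)
    if origin is None:
        first = times[0].to_pydatetime()
        origin = datetime.combine(first.date(), time(0, 0))

    durations = pd.to_numeric(df[dialect.event_duration_column], errors="coerce").to_numpy()
    codes = pd.to_numeric(df[dialect.event_code_column], errors="coerce").to_numpy()
    if not np.all(np.isfinite(durations)) or not np.all(np.isfinite(codes)):
        raise FormatError(f"{path}: non-numeric duration or activity code")

    records: list[EventRecord] = []
    code_map = {int(k): v for k, v in dialect.activity_codes.items()}
    for ts, dur, code in zip(times, durations, codes):
        if dur <= 0:
            raise FormatError(f"{path}: non-positive event duration {dur}")
        start_s = round((ts.to_pydatetime() - origin).total_seconds(), 1)
        activity = code_map.get(int(code))
        if activity is None:
            logger.warning("%s: unknown activity code %s mapped to 'other'", path, code)
            activity = ACTIVITY_OTHER
        records.append(EventRecord(start_s=start_s, duration_s=round(float(dur), 1), activity=activity))

    for prev, cur in zip(records, records[1:]):
        if cur.start_s < prev.start_s:
            raise FormatError(f"{path}: events out of time order at t={cur.start_s}s")
        if cur.start_s < prev.end_s - 1e-6:
            raise FormatError(f"{path}: overlapping events at t={cur.start_s}s")
    return records


def read_diary(path: str | Path, dialect: Dialect | None = None) -> list[DiaryDay]:
    """Read the sleep diary CSV (one row per monitored day)."""
    dialect = dialect or Dialect()
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no diary rows")
    date_col, wake_col, sleep_col = dialect.diary_columns
    _require_columns(df, dialect.diary_columns, path)

    days: list[DiaryDay] = []
    seen: set[_date] = set()
    for _, row in df.iterrows():
        try:
            d = _date.fromisoformat(str(row[date_col]).strip())
            wake = time.fromisoformat(str(row[wake_col]).strip())
            sleep = time.fromisoformat(str(row[sleep_col]).strip())
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable diary row ({exc})") from exc
        if d in seen:
            raise FormatError(f"{path}: duplicate diary date {d}")
        if sleep == wake:
            raise FormatError(f"{path}: zero-length waking window on {d}")
        seen.add(d)
        days.append(DiaryDay(date=d, wake=wake, sleep=sleep))
    days.sort(key=lambda day: day.date)
    return days
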
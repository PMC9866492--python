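"""Sedentary-bout extraction, posture classification and dwell-time binning.

The thigh monitor's events file defines sedentary bouts (thigh within 20 deg
of horizontal).  Bouts are intersected with the diary's waking windows: bouts
entirely inside sleep are dropped, partially overlapping bouts are clipped,
and a bout is *prolonged* when its clipped waking duration strictly exceeds
one hour.

Per-sample posture labels follow the angle thresholds
(boundary conventions: equality goes to the sitting / bent side):

* lying:           hip < 30 deg
* bent-knee sit:   hip >= 30 deg and knee >= 45 deg
* straight-leg sit: hip >= 30 deg and knee < 45 deg

Dwell time is accumulated per sample (one sample period each) into 15-degree
angle bins (<15, 15-30, ..., >75; lower-closed) and into posture classes,
split by bout-length class and calendar day, so a single bout whose posture
changes splits its time across labels and bins.  Degenerate (flagged) samples
are excluded from every tally and reported as a QC fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .activpal_io import ACTIVITY_SEDENTARY, DiaryDay, EventRecord
from .errors import ConsistencyError, MissingDiaryError
from .kinematics import JointAngleSeries

logger = logging.getLogger(__name__)

__all__ = [
    "HIP_SITTING_MIN_DEG",
    "KNEE_BENT_MIN_DEG",
    "PROLONGED_MIN_S",
    "SEDENTARY_INCLINE_MAX_DEG",
    "POSTURES",
    "LENGTH_CLASSES",
    "BIN_EDGES_DEG",
    "BIN_LABELS",
    "SedentaryBout",
    "extract_bouts",
    "classify_sample",
    "bin_dwell",
    "posture_dwell",
    "degenerate_fraction",
]

#: hip angles below this are lying; at/above, sitting
HIP_SITTING_MIN_DEG = 30.0
#: within sitting, knee angles at/above this are bent-knee
KNEE_BENT_MIN_DEG = 45.0
#: a sedentary bout is prolonged when clipped waking duration exceeds this
PROLONGED_MIN_S = 3600.0
#: thigh inclination from horizontal at/below which activity is sedentary
SEDENTARY_INCLINE_MAX_DEG = 20.0

POSTURES = ("bent_sit", "straight_sit", "lying")
LENGTH_CLASSES = ("prolonged", "non_prolonged")
#: lower-closed 15-degree bins; the last bin spans [75, 180]
BIN_EDGES_DEG = (15.0, 30.0, 45.0, 60.0, 75.0)
BIN_LABELS = ("<15", "15-30", "30-45", "45-60", "60-75", ">75")
JOINTS = ("hip", "knee")


@dataclass(frozen=True)
class SedentaryBout:
    """A sedentary event clipped to a waking window."""

    bout_id: int
    start_s: float  # seconds since recording start
    duration_s: float  # after clipping to waking time
    day: _date  # diary day owning the waking window
    prolonged: bool
    clipped: bool
    source_event: EventRecord | None = None

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def length_class(self) -> str:
        return "prolonged" if self.prolonged else "non_prolonged"


def extract_bouts(
    events: Sequence[EventRecord],
    diary: Sequence[DiaryDay],
    origin: datetime,
    prolonged_threshold_s: float = PROLONGED_MIN_S,
    lenient: bool = False,
) -> list[SedentaryBout]:
    """Intersect sedentary events with diary waking windows.

    Events wholly inside sleep are dropped; partial overlaps are clipped
    (``clipped=True``) and the prolonged flag is computed from the clipped
    duration (strictly > *prolonged_threshold_s*).  A sedentary event starting
    on a calendar day absent from the diary raises
    :class:`~triposture.errors.MissingDiaryError` (or is skipped with a
    warning when *lenient*).
    """
    windows = sorted(
        ((day.date, *day.waking_interval(origin)) for day in diary), key=lambda w: w[1]
    )
    for (_, _, e0), (_, s1, _) in zip(windows, windows[1:]):
        if s1 < e0 - 1e-9:
            raise ConsistencyError("diary waking windows overlap")
    diary_dates = {day.date for day in diary}

    bouts: list[SedentaryBout] = []
    bout_id = 0
    for ev in events:
        if ev.activity != ACTIVITY_SEDENTARY:
            continue
        ev_date = (origin + timedelta(seconds=ev.start_s)).date()
        if ev_date not in diary_dates:
            if not lenient:
                raise MissingDiaryError(f"no diary row for {ev_date} (event at {ev.start_s} s)")
            logger.warning("skipping sedentary event on %s: no diary row", ev_date)
            continue
        for day, w0, w1 in windows:
            lo = max(ev.start_s, w0)
            hi = min(ev.end_s, w1)
            if hi - lo <= 1e-9:
                continue
            clipped = lo > ev.start_s + 1e-9 or hi < ev.end_s - 1e-9
            bouts.append(
                SedentaryBout(
                    bout_id=bout_id,
                    start_s=lo,
                    duration_s=hi - lo,
                    day=day,
                    prolonged=(hi - lo) > prolonged_threshold_s,
                    clipped=clipped,
                    source_event=ev,
                )
            )
            bout_id += 1
    return bouts


def classify_sample(
    hip_deg,
    knee_deg,
    hip_sitting_min: float = HIP_SITTING_MIN_DEG,
    knee_bent_min: float = KNEE_BENT_MIN_DEG,
):
    """Posture label(s) for hip/knee angle(s) in degrees.

    Vectorised; returns a string for scalars, an object array otherwise.
    Equality at a threshold resolves to sitting (hip) and bent (knee).
    """
    hip = np.asarray(hip_deg, dtype=np.float64)
    knee = np.asarray(knee_deg, dtype=np.float64)
    labels = np.where(
        hip < hip_sitting_min,
        "lying",
        np.where(knee >= knee_bent_min, "bent_sit", "straight_sit"),
    )
    return str(labels[()]) if labels.ndim == 0 else labels


def _bout_lookup(bouts: Sequence[SedentaryBout]) -> tuple[dict[int, int], list[tuple[_date, str]]]:
    """Map bout_id -> (day, length_class) key index."""
    keys: list[tuple[_date, str]] = []
    key_index: dict[tuple[_date, str], int] = {}
    bout_to_key: dict[int, int] = {}
    for b in bouts:
        key = (b.day, b.length_class)
        if key not in key_index:
            key_index[key] = len(keys)
            keys.append(key)
        bout_to_key[b.bout_id] = key_index[key]
    return bout_to_key, keys


def _sample_keys(series: JointAngleSeries, bout_to_key: dict[int, int]) -> np.ndarray:
    ids = series.bout_id
    unique = np.unique(ids)
    missing = [int(i) for i in unique if int(i) not in bout_to_key]
    if missing:
        raise ConsistencyError(f"samples reference unknown bout id(s) {missing}")
    mapper = {i: k for i, k in bout_to_key.items()}
    lut_ids = np.array(sorted(mapper), dtype=np.int64)
    lut_keys = np.array([mapper[i] for i in sorted(mapper)], dtype=np.int64)
    return lut_keys[np.searchsorted(lut_ids, ids)]


def bin_dwell(series: JointAngleSeries, bouts: Sequence[SedentaryBout]) -> pd.DataFrame:
    """Dwell seconds per 15-degree angle bin, joint, day and bout-length class.

    Each non-degenerate sample contributes one sample period to the bin
    containing its angle (bins lower-closed, last bin [75, 180]).  Returns a
    tidy frame over the full (day, class, joint, bin) grid with zeros filled.
    """
    bout_to_key, keys = _bout_lookup(bouts)
    sample_keys = _sample_keys(series, bout_to_key)
    valid = ~series.degenerate
    edges = np.asarray(BIN_EDGES_DEG)
    n_bins = len(BIN_LABELS)

    rows = []
    for joint, angles in (("hip", series.hip_deg), ("knee", series.knee_deg)):
        bin_idx = np.searchsorted(edges, angles[valid], side="right")
        flat = sample_keys[valid] * n_bins + bin_idx
        counts = np.bincount(flat, minlength=len(keys) * n_bins)
        for k, (day, cls) in enumerate(keys):
            for b in range(n_bins):
                rows.append(
                    (day, joint, BIN_LABELS[b], cls, counts[k * n_bins + b] / series.sample_rate)
                )
    return pd.DataFrame(rows, columns=["day", "joint", "bin", "length_class", "dwell_s"])


def posture_dwell(series: JointAngleSeries, bouts: Sequence[SedentaryBout]) -> pd.DataFrame:
    """Dwell seconds per posture label, day and bout-length class (tidy frame)."""
    bout_to_key, keys = _bout_lookup(bouts)
    sample_keys = _sample_keys(series, bout_to_key)
    valid = ~series.degenerate

    labels = classify_sample(series.hip_deg[valid], series.knee_deg[valid])
    posture_idx = np.searchsorted(np.array(sorted(POSTURES)), labels)
    order = {p: i for i, p in enumerate(sorted(POSTURES))}
    n_post = len(POSTURES)
    flat = sample_keys[valid] * n_post + posture_idx
    counts = np.bincount(flat, minlength=len(keys) * n_post)

    rows = []
    for k, (day, cls) in enumerate(keys):
        for posture in POSTURES:
            rows.append(
                (day, posture, cls, counts[k * n_post + order[posture]] / series.sample_rate)
            )
    return pd.DataFrame(rows, columns=["day", "posture", "length_class", "dwell_s"])


def degenerate_fraction(
    series: JointAngleSeries, bouts: Sequence[SedentaryBout]
) -> pd.DataFrame:
    """QC: fraction of sedentary samples flagged degenerate, per day."""
    bout_to_key, keys = _bout_lookup(bouts)
    sample_keys = _sample_keys(series, bout_to_key)
    days = sorted({d for d, _ in keys})
    day_index = {d: i for i, d in enumerate(days)}
    key_day = np.array([day_index[d] for d, _ in keys], dtype=np.int64)
    sample_day = key_day[sample_keys]
    total = np.bincount(sample_day, minlength=len(days))
    bad = np.bincount(sample_day[series.degenerate], minlength=len(days))
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, bad / np.maximum(total, 1), 0.0)
    return pd.DataFrame({"day": days, "n_samples": total, "degenerate_fraction": frac})


def bout_table(bouts: Sequence[SedentaryBout], origin: datetime) -> pd.DataFrame:
    """Bout-level export: start time-of-day, duration, flags (one row per bout)."""
    rows = []
    for b in bouts:
        start_dt = origin + timedelta(seconds=b.start_s)
        rows.append(
            (
                b.bout_id,
                b.day.isoformat(),
                start_dt.time().isoformat(timespec="seconds"),
                b.duration_s / 60.0,
                b.length_class,
                b.clipped,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["bout_id", "day", "start_time", "duration_min", "length_class", "clipped"],
    )
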
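"""Ground-truth posture scenarios and rendering to the three input file kinds.

A :class:`SyntheticScenario` is an ordered list of piecewise-constant posture
segments (sleep lying, awake lying, bent-knee sitting, straight-legged
sitting, upright) that tile a multi-day recording.  Each segment carries the
nominal hip and knee flexion angles and the thigh inclination from
horizontal; sedentary states keep the thigh within 20 degrees of horizontal,
upright does not, so the emitted events file obeys the thigh monitor's
sedentary rule exactly.

The orientation model is planar (sagittal): all rotations are about the
medio-lateral axis, so each monitor's gravity vector is
``(cos a, 0, sin a)`` g for a segment orientation ``a`` (thigh: its
inclination; torso: inclination + hip angle; shin: inclination + knee angle)
and the inter-monitor angles are analytic.  Rendering adds isotropic Gaussian
noise and a slow within-segment angular wander per monitor, then quantizes
through the inverse device count map so file round-trips are bit-exact.

Default study conditions emulate a free-living cohort of healthy adults:
bent-knee sitting 439 min/day, straight-legged sitting 113 min/day, lying
69 min/day, about a third of sedentary time in prolonged (>1 h) bouts, short
bouts of 8.8 +/- 1.8 min, 16 h waking days (07:00-23:00).

``ground_truth`` computes the exact per-posture / per-bin dwell analytically
from the segments on the sample grid, with no rendering, including its own
independent event/waking-window intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activpal_io import (
    ACTIVITY_SEDENTARY,
    ACTIVITY_UPRIGHT,
    AccelTrace,
    DeviceVersion,
    Dialect,
    DiaryDay,
    EventRecord,
    Site,
    counts_to_g,
    g_to_counts,
)
from .errors import ConfigurationError
from .kinematics import sample_index_range
from .posture import (
    BIN_EDGES_DEG,
    BIN_LABELS,
    SEDENTARY_INCLINE_MAX_DEG,
)
from .summary import PostureSummary, daily_summary

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "SyntheticScenario",
    "Rendered",
    "GroundTruth",
    "make_scenario",
    "render",
    "ground_truth",
    "realized_state_mix",
    "write_accel",
    "write_events",
    "write_diary",
    "write_rendered",
    "DEFAULT_STATE_MIX",
    "STATE_ANGLES",
    "SEDENTARY_STATES",
]

#: nominal (hip, knee, thigh-incline) degrees per state; chosen well inside the
#: posture thresholds (hip 30, knee 45) and >= 5 deg from every 15-deg bin edge
STATE_ANGLES: dict[str, tuple[float, float, float]] = {
    "sleep_lying": (10.0, 10.0, 0.0),
    "lying": (10.0, 10.0, 0.0),
    "bent_sit": (90.0, 90.0, 0.0),
    "straight_sit": (90.0, 20.0, 0.0),
    "upright": (0.0, 0.0, 90.0),
}

SEDENTARY_STATES = frozenset({"sleep_lying", "lying", "bent_sit", "straight_sit"})
POSTURE_STATES = ("bent_sit", "straight_sit", "lying")

#: default waking min/day per sedentary posture (free-living cohort conditions)
DEFAULT_STATE_MIX: dict[str, float] = {"bent_sit": 439.0, "straight_sit": 113.0, "lying": 69.0}
#: default fraction of sedentary time accumulated in prolonged (>1 h) bouts
DEFAULT_PROLONGED_FRACTION = 0.33
#: short (non-prolonged) bout length distribution, minutes
NON_PROLONGED_BOUT_MEAN_MIN = 8.8
NON_PROLONGED_BOUT_SD_MIN = 1.8

_DEFAULT_WAKE = time(7, 0)
_DEFAULT_SLEEP = time(23, 0)
_DEFAULT_START = datetime(2023, 1, 2)

_GAP_MIN = 1.0  # minimum upright gap between sedentary bouts, minutes
_EDGE_MIN = 2.0  # upright buffer after wake-up and before sleep, minutes


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant posture interval."""

    state: str
    duration_s: float
    hip_deg: float
    knee_deg: float
    thigh_incline_deg: float

    @property
    def sedentary(self) -> bool:
        return self.state in SEDENTARY_STATES


@dataclass
class SyntheticScenario:
    """A reproducible ground-truth posture schedule."""

    seed: int
    days: int
    segments: list[Segment]
    noise_sd_g: float = 0.02
    jitter_sd_deg: float = 2.0
    device_version: DeviceVersion = DeviceVersion.AP3
    sample_rate: float = 20.0
    start: datetime = _DEFAULT_START
    wake: time = _DEFAULT_WAKE
    sleep: time = _DEFAULT_SLEEP

    def validate(self) -> None:
        total = sum(s.duration_s for s in self.segments)
        if abs(total - self.days * 86400.0) > 1e-6:
            raise ConfigurationError(
                f"segments span {total} s, expected {self.days * 86400.0} s"
            )
        for s in self.segments:
            if s.duration_s <= 0:
                raise ConfigurationError("segment durations must be positive")
            if s.sedentary and s.thigh_incline_deg > SEDENTARY_INCLINE_MAX_DEG:
                raise ConfigurationError(
                    f"sedentary state {s.state} with thigh incline {s.thigh_incline_deg} deg"
                )
            if not s.sedentary and s.thigh_incline_deg <= SEDENTARY_INCLINE_MAX_DEG:
                raise ConfigurationError("upright segment with sedentary thigh incline")
            if s.state == "lying" and not s.hip_deg < 30.0:
                raise ConfigurationError("lying segment must have hip < 30 deg")
            if s.state == "bent_sit" and not (s.hip_deg >= 30.0 and s.knee_deg >= 45.0):
                raise ConfigurationError("bent_sit segment violates hip/knee thresholds")
            if s.state == "straight_sit" and not (s.hip_deg >= 30.0 and s.knee_deg < 45.0):
                raise ConfigurationError("straight_sit segment violates hip/knee thresholds")

    def diary(self) -> list[DiaryDay]:
        d0 = self.start.date()
        return [
            DiaryDay(date=d0 + timedelta(days=i), wake=self.wake, sleep=self.sleep)
            for i in range(self.days)
        ]

    def segment_starts_s(self) -> np.ndarray:
        durs = np.array([s.duration_s for s in self.segments])
        return np.concatenate([[0.0], np.cumsum(durs)])[:-1]


def _seconds_of_day(t: time) -> float:
    return t.hour * 3600.0 + t.minute * 60.0 + t.second


def make_scenario(
    seed: int,
    days: int = 7,
    state_mix: Mapping[str, float] | None = None,
    prolonged_fraction: float = DEFAULT_PROLONGED_FRACTION,
    noise_sd_g: float = 0.02,
    jitter_sd_deg: float = 2.0,
    device_version: DeviceVersion = DeviceVersion.AP3,
    sample_rate: float = 20.0,
    start: datetime = _DEFAULT_START,
    wake: time = _DEFAULT_WAKE,
    sleep: time = _DEFAULT_SLEEP,
) -> SyntheticScenario:
    """Build a reproducible scenario hitting target min/day per posture.

    *state_mix* gives waking min/day for each of bent_sit / straight_sit /
    lying; *prolonged_fraction* is the share of each posture's time scheduled
    as prolonged (>1 h) bouts.  Bouts are planned at the week level: postures
    whose prolonged share is below one bout-hour per day still receive a few
    >1 h bouts on some days and none on others (which is also what makes
    day-level prolonged averages smaller than one hour under zero-filling).
    Realized totals land within about one mean segment duration of the
    targets.  Identical arguments (including *seed*) yield identical
    scenarios.
    """
    mix = dict(DEFAULT_STATE_MIX if state_mix is None else state_mix)
    unknown = set(mix) - set(POSTURE_STATES)
    if unknown:
        raise ConfigurationError(f"unknown posture states in state_mix: {sorted(unknown)}")
    if any(v < 0 for v in mix.values()):
        raise ConfigurationError("state_mix targets must be non-negative")
    if not 0.0 <= prolonged_fraction <= 1.0:
        raise ConfigurationError("prolonged_fraction must be in [0, 1]")
    if days < 1:
        raise ConfigurationError("need at least one day")
    if not wake < sleep:
        raise ConfigurationError("generator requires wake < sleep within the day")

    wake_s = _seconds_of_day(wake)
    sleep_s = _seconds_of_day(sleep)
    waking_min = (sleep_s - wake_s) / 60.0
    total_target = sum(mix.values())
    # reserve the edge buffers plus ~one gap per expected short bout
    upright_reserve = 2 * _EDGE_MIN + _GAP_MIN * max(
        1.0, (1 - prolonged_fraction) * total_target / NON_PROLONGED_BOUT_MEAN_MIN
    )
    if total_target + upright_reserve > waking_min:
        raise ConfigurationError(
            f"infeasible state_mix: {total_target:.0f} sedentary min/day plus "
            f"{upright_reserve:.0f} min upright reserve exceeds the "
            f"{waking_min:.0f} min waking window"
        )

    rng = np.random.default_rng(seed)

    # ---- week-level bout pool -------------------------------------------
    pool: list[list] = []  # [state, duration_min, prolonged]
    for state in POSTURE_STATES:
        week_total = mix.get(state, 0.0) * days
        p_budget = prolonged_fraction * week_total
        p_assigned = 0.0
        while p_budget - p_assigned >= 61.0:
            d = float(rng.uniform(65.0, 110.0))
            rem = p_budget - p_assigned
            if rem - d < 61.0:
                d = min(rem, 110.0)
            pool.append([state, d, True])
            p_assigned += d
        np_budget = week_total - p_assigned
        while np_budget > 1.0:
            d = float(np.clip(rng.normal(NON_PROLONGED_BOUT_MEAN_MIN, NON_PROLONGED_BOUT_SD_MIN), 3.0, 30.0))
            if np_budget - d < 3.0:
                d = min(np_budget, 59.0)
            pool.append([state, d, False])
            np_budget -= d

    # ---- pack bouts into days (largest-capacity-first) -------------------
    day_cap = np.full(days, waking_min - 2 * _EDGE_MIN)
    day_bouts: list[list[list]] = [[] for _ in range(days)]
    prolonged_pool = sorted((b for b in pool if b[2]), key=lambda b: -b[1])
    short_pool = [b for b in pool if not b[2]]
    rng.shuffle(short_pool)
    for b in prolonged_pool + short_pool:
        d = int(np.argmax(day_cap))
        need = b[1] + _GAP_MIN
        if day_cap[d] >= need:
            day_bouts[d].append(b)
            day_cap[d] -= need
            continue
        trim = day_cap[d] - _GAP_MIN
        if b[2] and trim >= 61.0:
            day_bouts[d].append([b[0], trim, True])
            day_cap[d] -= trim + _GAP_MIN
        elif not b[2] and trim >= 3.0:
            day_bouts[d].append([b[0], min(trim, 59.0), False])
            day_cap[d] -= min(trim, 59.0) + _GAP_MIN
        else:
            logger.warning("dropping %s bout of %.1f min: no day capacity", b[0], b[1])

    # ---- realize per-day segment sequences ------------------------------
    waking_s = sleep_s - wake_s
    segments: list[Segment] = []
    for i in range(days):
        blist = list(day_bouts[i])
        rng.shuffle(blist)
        sed_total = sum(b[1] for b in blist)
        upright_total = waking_min - sed_total
        n_gaps = len(blist) + 1
        extra = upright_total - _GAP_MIN * n_gaps
        if extra < 0:
            raise ConfigurationError("internal packing error: negative upright slack")
        weights = rng.dirichlet(np.ones(n_gaps)) if n_gaps > 1 else np.array([1.0])
        gaps = _GAP_MIN + weights * extra

        pieces: list[tuple[str, float]] = [("upright", gaps[0])]
        for b, gap in zip(blist, gaps[1:]):
            pieces.append((b[0], b[1]))
            pieces.append(("upright", gap))
        secs = [max(1, int(round(p * 60.0))) for _, p in pieces]
        drift = int(round(waking_s)) - sum(secs)
        secs[-1] += drift  # absorb rounding in the final upright gap
        if secs[-1] <= 0:
            raise ConfigurationError("internal packing error: final gap non-positive")

        segments.append(_make_segment("sleep_lying", wake_s))
        for (state, _), dur in zip(pieces, secs):
            segments.append(_make_segment(state, float(dur)))
        segments.append(_make_segment("sleep_lying", 86400.0 - sleep_s))

    scenario = SyntheticScenario(
        seed=seed,
        days=days,
        segments=segments,
        noise_sd_g=noise_sd_g,
        jitter_sd_deg=jitter_sd_deg,
        device_version=DeviceVersion(device_version),
        sample_rate=sample_rate,
        start=start,
        wake=wake,
        sleep=sleep,
    )
    scenario.validate()
    return scenario


def _make_segment(state: str, duration_s: float) -> Segment:
    hip, knee, incline = STATE_ANGLES[state]
    return Segment(
        state=state, duration_s=duration_s, hip_deg=hip, knee_deg=knee, thigh_incline_deg=incline
    )


def realized_state_mix(scenario: SyntheticScenario) -> dict[str, float]:
    """Scheduled waking min/day per posture state (upright included)."""
    totals: dict[str, float] = {}
    for s in scenario.segments:
        if s.state == "sleep_lying":
            continue
        totals[s.state] = totals.get(s.state, 0.0) + s.duration_s / 60.0
    return {k: v / scenario.days for k, v in totals.items()}


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass
class Rendered:
    """In-memory rendering of a scenario: the three traces plus events + diary."""

    torso: AccelTrace
    thigh: AccelTrace
    shin: AccelTrace
    events: list[EventRecord]
    diary: list[DiaryDay]
    scenario: SyntheticScenario


def _segment_sample_counts(scenario: SyntheticScenario) -> np.ndarray:
    fs = scenario.sample_rate
    starts = scenario.segment_starts_s()
    counts = np.empty(len(scenario.segments), dtype=np.int64)
    for k, (s0, seg) in enumerate(zip(starts, scenario.segments)):
        i0, i1 = sample_index_range(s0, s0 + seg.duration_s, fs)
        counts[k] = i1 - i0
    return counts


def _slow_wander(counts: np.ndarray, sd_deg: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Per-segment smooth angular wander: 60 s control points, linear interp."""
    out = np.empty(int(counts.sum()))
    pos = 0
    for m in counts:
        m = int(m)
        n_ctrl = max(2, int(m / (60.0 * fs)) + 2)
        ctrl_x = np.linspace(0, m - 1, n_ctrl)
        ctrl_y = rng.normal(0.0, sd_deg, n_ctrl)
        out[pos : pos + m] = np.interp(np.arange(m), ctrl_x, ctrl_y)
        pos += m
    return out


def events_from_segments(scenario: SyntheticScenario) -> list[EventRecord]:
    """Events file content: one record per maximal run of same-class segments."""
    records: list[EventRecord] = []
    starts = scenario.segment_starts_s()
    run_start: float | None = None
    run_sed: bool | None = None
    for s0, seg in zip(starts, scenario.segments):
        if run_sed is None or seg.sedentary != run_sed:
            if run_sed is not None:
                records.append(
                    EventRecord(
                        start_s=round(run_start, 1),
                        duration_s=round(s0 - run_start, 1),
                        activity=ACTIVITY_SEDENTARY if run_sed else ACTIVITY_UPRIGHT,
                    )
                )
            run_start, run_sed = s0, seg.sedentary
    end = scenario.days * 86400.0
    records.append(
        EventRecord(
            start_s=round(run_start, 1),
            duration_s=round(end - run_start, 1),
            activity=ACTIVITY_SEDENTARY if run_sed else ACTIVITY_UPRIGHT,
        )
    )
    return records


def render(scenario: SyntheticScenario, quantize: bool = True) -> Rendered:
    """Render a scenario into three monitor traces plus events and diary.

    Each monitor's signal is the unit gravity vector implied by its segment
    orientation (planar model) times 1 g, plus isotropic Gaussian noise
    (``noise_sd_g``) and slow per-monitor angular wander (``jitter_sd_deg``),
    quantized through the inverse device count map unless *quantize* is
    False (useful for geometry-only checks; files always quantize).
    """
    scenario.validate()
    fs = scenario.sample_rate
    counts = _segment_sample_counts(scenario)
    rng = np.random.default_rng([int(scenario.seed) % (2**31), 202])

    hip = np.repeat([s.hip_deg for s in scenario.segments], counts)
    knee = np.repeat([s.knee_deg for s in scenario.segments], counts)
    incline = np.repeat([s.thigh_incline_deg for s in scenario.segments], counts)
    n = hip.shape[0]

    orientations = {
        Site.TORSO: incline + hip,
        Site.THIGH: incline,
        Site.SHIN: incline + knee,
    }
    del hip, knee, incline

    traces: dict[Site, AccelTrace] = {}
    for site, alpha in orientations.items():
        if scenario.jitter_sd_deg > 0:
            alpha = alpha + _slow_wander(counts, scenario.jitter_sd_deg, fs, rng)
        rad = np.radians(alpha)
        g = np.empty((n, 3))
        g[:, 0] = np.cos(rad)
        g[:, 1] = 0.0
        g[:, 2] = np.sin(rad)
        del rad
        if scenario.noise_sd_g > 0:
            g += rng.normal(0.0, scenario.noise_sd_g, (n, 3))
        if quantize:
            g = counts_to_g(
                g_to_counts(g, scenario.device_version), scenario.device_version
            )
        traces[site] = AccelTrace(
            site=site,
            start=scenario.start,
            samples=g,
            sample_rate=fs,
            device_version=scenario.device_version,
        )
    orientations.clear()

    return Rendered(
        torso=traces[Site.TORSO],
        thigh=traces[Site.THIGH],
        shin=traces[Site.SHIN],
        events=events_from_segments(scenario),
        diary=scenario.diary(),
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Exact dwell per posture/bin/bout-class, computed from segments alone."""

    posture_dwell: pd.DataFrame  # day, posture, length_class, dwell_s
    bin_dwell: pd.DataFrame  # day, joint, bin, length_class, dwell_s
    summary: PostureSummary
    bouts: pd.DataFrame  # day, start_s, duration_s, prolonged, clipped
    prolonged_fraction: float


def _bin_label(angle_deg: float) -> str:
    idx = int(np.searchsorted(np.asarray(BIN_EDGES_DEG), angle_deg, side="right"))
    return BIN_LABELS[idx]


def ground_truth(
    scenario: SyntheticScenario, prolonged_threshold_s: float = 3600.0
) -> GroundTruth:
    """Exact dwell tallies from the schedule, on the sample grid, no rendering.

    Uses its own interval arithmetic (independent of the pipeline's bout
    extraction): sedentary runs of segments are intersected with the diary
    waking windows, prolonged flags come from the clipped durations, and each
    clipped posture piece contributes its exact number of sample periods.
    Angles are the segments' nominal values.
    """
    scenario.validate()
    fs = scenario.sample_rate
    starts = scenario.segment_starts_s()
    wake_s = _seconds_of_day(scenario.wake)
    sleep_s = _seconds_of_day(scenario.sleep)
    d0 = scenario.start.date()
    windows = [
        (d0 + timedelta(days=i), i * 86400.0 + wake_s, i * 86400.0 + sleep_s)
        for i in range(scenario.days)
    ]

    # maximal sedentary runs with their constituent pieces
    runs: list[tuple[float, float, list[tuple[Segment, float, float]]]] = []
    cur: list[tuple[Segment, float, float]] = []
    for s0, seg in zip(starts, scenario.segments):
        if seg.sedentary:
            cur.append((seg, s0, s0 + seg.duration_s))
        elif cur:
            runs.append((cur[0][1], cur[-1][2], cur))
            cur = []
    if cur:
        runs.append((cur[0][1], cur[-1][2], cur))

    posture_acc: dict[tuple[_date, str, str], int] = {}
    bin_acc: dict[tuple[_date, str, str, str], int] = {}
    bout_rows = []
    for ev_start, ev_end, pieces in runs:
        for day, w0, w1 in windows:
            lo, hi = max(ev_start, w0), min(ev_end, w1)
            if hi - lo <= 1e-9:
                continue
            prolonged = (hi - lo) > prolonged_threshold_s
            cls = "prolonged" if prolonged else "non_prolonged"
            clipped = lo > ev_start + 1e-9 or hi < ev_end - 1e-9
            bout_rows.append((day, lo, hi - lo, prolonged, clipped))
            for seg, p0, p1 in pieces:
                a, b = max(p0, lo), min(p1, hi)
                if b - a <= 1e-9:
                    continue
                i0, i1 = sample_index_range(a, b, fs)
                n_samp = i1 - i0
                posture = "lying" if seg.state == "sleep_lying" else seg.state
                posture_acc[(day, posture, cls)] = (
                    posture_acc.get((day, posture, cls), 0) + n_samp
                )
                for joint, angle in (("hip", seg.hip_deg), ("knee", seg.knee_deg)):
                    key = (day, joint, _bin_label(angle), cls)
                    bin_acc[key] = bin_acc.get(key, 0) + n_samp

    posture_df = pd.DataFrame(
        [(d, p, c, n / fs) for (d, p, c), n in sorted(posture_acc.items(), key=str)],
        columns=["day", "posture", "length_class", "dwell_s"],
    )
    bin_df = pd.DataFrame(
        [(d, j, b, c, n / fs) for (d, j, b, c), n in sorted(bin_acc.items(), key=str)],
        columns=["day", "joint", "bin", "length_class", "dwell_s"],
    )
    bouts = pd.DataFrame(
        bout_rows, columns=["day", "start_s", "duration_s", "prolonged", "clipped"]
    )
    total = bouts["duration_s"].sum()
    prolonged_frac = (
        float(bouts.loc[bouts["prolonged"], "duration_s"].sum() / total) if total else 0.0
    )
    summary = daily_summary(posture_df, scenario.diary(), participant_id="truth")
    return GroundTruth(
        posture_dwell=posture_df,
        bin_dwell=bin_df,
        summary=summary,
        bouts=bouts,
        prolonged_fraction=prolonged_frac,
    )


# ---------------------------------------------------------------------------
# writers (dialects identical to the readers)
# ---------------------------------------------------------------------------

_TIME_FORMAT = "%Y-%m-%d %H:%M:%S.%f"


def write_accel(trace: AccelTrace, path: str | Path, dialect: Dialect | None = None) -> None:
    """Write a trace as a raw counts CSV; quantizes through the device map."""
    dialect = dialect or Dialect()
    counts = g_to_counts(trace.samples, trace.device_version, dialect)
    times = pd.date_range(
        trace.start, periods=trace.n_samples, freq=pd.Timedelta(seconds=1.0 / trace.sample_rate)
    )
    df = pd.DataFrame({dialect.time_column: times})
    for j, col in enumerate(dialect.axis_columns):
        df[col] = counts[:, j]
    df.to_csv(path, index=False, date_format=_TIME_FORMAT)


def write_events(
    records: Sequence[EventRecord],
    path: str | Path,
    origin: datetime,
    dialect: Dialect | None = None,
) -> None:
    dialect = dialect or Dialect()
    df = pd.DataFrame(
        {
            dialect.event_time_column: [
                (origin + timedelta(seconds=r.start_s)).strftime(_TIME_FORMAT) for r in records
            ],
            dialect.event_duration_column: [f"{r.duration_s:.1f}" for r in records],
            dialect.event_code_column: [dialect.code_for(r.activity) for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_diary(diary: Sequence[DiaryDay], path: str | Path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    date_col, wake_col, sleep_col = dialect.diary_columns
    df = pd.DataFrame(
        {
            date_col: [d.date.isoformat() for d in diary],
            wake_col: [d.wake.isoformat(timespec="minutes") for d in diary],
            sleep_col: [d.sleep.isoformat(timespec="minutes") for d in diary],
        }
    )
    df.to_csv(path, index=False)


def write_rendered(
    rendered: Rendered, out_dir: str | Path, dialect: Dialect | None = None
) -> dict[str, Path]:
    """Write all five input files of a rendered scenario into *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "torso": out / "torso.csv",
        "thigh": out / "thigh.csv",
        "shin": out / "shin.csv",
        "events": out / "events.csv",
        "diary": out / "diary.csv",
    }
    write_accel(rendered.torso, paths["torso"], dialect)
    write_accel(rendered.thigh, paths["thigh"], dialect)
    write_accel(rendered.shin, paths["shin"], dialect)
    write_events(rendered.events, paths["events"], rendered.scenario.start, dialect)
    write_diary(rendered.diary, paths["diary"], dialect)
    return paths
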
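"""Bout extraction, posture classification and dwell binning."""

from __future__ import annotations

from datetime import date, datetime, time

import numpy as np
import pytest

from triposture.activpal_io import DiaryDay, EventRecord
from triposture.errors import ConsistencyError, MissingDiaryError
from triposture.kinematics import JointAngleSeries
from triposture.posture import (
    BIN_LABELS,
    SEDENTARY_INCLINE_MAX_DEG,
    SedentaryBout,
    bin_dwell,
    classify_sample,
    extract_bouts,
    posture_dwell,
)

ORIGIN = datetime(2023, 1, 2)
DAY1 = date(2023, 1, 2)
DIARY = [DiaryDay(DAY1, time(7, 0), time(23, 0)), DiaryDay(date(2023, 1, 3), time(7, 0), time(23, 0))]

H = 3600.0


def _sed(start_h, dur_min):
    return EventRecord(start_s=start_h * H, duration_s=dur_min * 60.0, activity="sedentary")


# ---------------------------------------------------------------------------
# bout extraction
# ---------------------------------------------------------------------------


def test_waking_bout_inside_window_is_kept_unchanged():
    bouts = extract_bouts([_sed(10, 30)], DIARY, ORIGIN)
    assert len(bouts) == 1
    b = bouts[0]
    assert (b.start_s, b.duration_s) == (10 * H, 1800.0)
    assert not b.prolonged and not b.clipped and b.day == DAY1


def test_prolonged_flag_is_strictly_greater_than_one_hour():
    bouts = extract_bouts([_sed(10, 90)], DIARY, ORIGIN)
    assert bouts[0].prolonged
    exactly = extract_bouts([_sed(12, 60)], DIARY, ORIGIN)
    assert not exactly[0].prolonged  # exactly 1 h is not prolonged


def test_bout_clipped_at_sleep_loses_its_prolonged_status():
    """A 90 min bout whose last 40 min fall after sleep onset becomes a
    50 min clipped, non-prolonged bout (interval intersection)."""
    bouts = extract_bouts([_sed(22 + 10 / 60, 90)], DIARY, ORIGIN)  # 22:10 -> 23:40
    assert len(bouts) == 1
    b = bouts[0]
    assert b.duration_s == pytest.approx(50 * 60.0)
    assert b.clipped and not b.prolonged


def test_fully_sleeping_bout_is_dropped_and_upright_ignored():
    events = [
        EventRecord(start_s=1 * H, duration_s=3 * H, activity="sedentary"),  # night
        EventRecord(start_s=12 * H, duration_s=1 * H, activity="upright"),
    ]
    assert extract_bouts(events, DIARY, ORIGIN) == []


def test_bout_spanning_sleep_is_split_across_waking_windows():
    # 22:00 day1 -> 08:00 day2 sedentary run: 1 h before sleep + 1 h after wake
    bouts = extract_bouts([EventRecord(22 * H, 10 * H, "sedentary")], DIARY, ORIGIN)
    assert [(b.day, b.duration_s, b.clipped) for b in bouts] == [
        (DAY1, H, True),
        (date(2023, 1, 3), H, True),
    ]


def test_missing_diary_day_errors_unless_lenient(caplog):
    events = [EventRecord((24 + 10) * H, 1800.0, "sedentary")]
    diary = [DIARY[0]]  # second day absent
    with pytest.raises(MissingDiaryError):
        extract_bouts(events, diary, ORIGIN)
    assert extract_bouts(events, diary, ORIGIN, lenient=True) == []


# ---------------------------------------------------------------------------
# posture classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "hip, knee, label",
    [
        (10.0, 10.0, "lying"),
        (90.0, 90.0, "bent_sit"),
        (90.0, 20.0, "straight_sit"),
        (29.999, 179.0, "lying"),  # hip below the cut wins regardless of knee
        (30.0, 45.0, "bent_sit"),  # boundary convention: equality -> sitting, bent
        (30.0, 44.999, "straight_sit"),
    ],
)
def test_classify_sample_thresholds_and_boundaries(hip, knee, label):
    assert classify_sample(hip, knee) == label


def test_classify_sample_vectorised_matches_scalar():
    hips = np.array([10.0, 90.0, 90.0, 30.0])
    knees = np.array([10.0, 90.0, 20.0, 45.0])
    labels = classify_sample(hips, knees)
    assert list(labels) == [classify_sample(h, k) for h, k in zip(hips, knees)]


# ---------------------------------------------------------------------------
# dwell binning
# ---------------------------------------------------------------------------


def _series(hip, knee, bout_ids, fs=20.0):
    hip = np.asarray(hip, dtype=float)
    return JointAngleSeries(
        times_s=np.arange(hip.size) / fs,
        hip_deg=hip,
        knee_deg=np.asarray(knee, dtype=float),
        bout_id=np.asarray(bout_ids, dtype=np.int64),
        sample_rate=fs,
    )


def _bout(bout_id, prolonged=False, day=DAY1):
    return SedentaryBout(
        bout_id=bout_id, start_s=0.0, duration_s=600.0, day=day, prolonged=prolonged, clipped=False
    )


def test_constant_angle_block_lands_in_one_bin():
    """10 min of samples at 50 deg knee -> 600 s in knee bin 45-60."""
    n = 12000  # 10 min at 20 Hz
    series = _series(np.full(n, 80.0), np.full(n, 50.0), np.zeros(n))
    df = bin_dwell(series, [_bout(0)])
    knee = df[(df.joint == "knee")].set_index("bin")["dwell_s"]
    assert knee["45-60"] == pytest.approx(600.0)
    assert knee.drop("45-60").sum() == 0.0


def test_bin_edges_are_lower_closed():
    series = _series([45.0, 44.999, 75.0, 180.0], [15.0, 14.999, 0.0, 90.0], [0, 0, 0, 0])
    df = bin_dwell(series, [_bout(0)])
    hip = df[df.joint == "hip"].set_index("bin")["dwell_s"] * 20.0  # -> sample counts
    knee = df[df.joint == "knee"].set_index("bin")["dwell_s"] * 20.0
    assert hip["45-60"] == 1 and hip["30-45"] == 1 and hip[">75"] == 2
    assert knee["15-30"] == 1 and knee["<15"] == 2 and knee[">75"] == 1


def test_bin_dwell_matches_bruteforce_tally(rng):
    """Mixed random series vs an exhaustive per-sample counting oracle."""
    n = 5000
    hip = rng.uniform(0, 180, n)
    knee = rng.uniform(0, 180, n)
    hip[rng.random(n) < 0.05] = np.nan  # degenerate samples
    bout_ids = rng.integers(0, 3, n)
    bouts = [_bout(0), _bout(1, prolonged=True), _bout(2, day=date(2023, 1, 3))]
    series = _series(hip, knee, bout_ids)

    df = bin_dwell(series, bouts)
    lookup = {b.bout_id: b for b in bouts}
    edges = [15.0, 30.0, 45.0, 60.0, 75.0]
    oracle: dict[tuple, int] = {}
    for i in range(n):
        if np.isnan(hip[i]) or np.isnan(knee[i]):
            continue
        b = lookup[int(bout_ids[i])]
        for joint, ang in (("hip", hip[i]), ("knee", knee[i])):
            k = sum(ang >= e for e in edges)
            key = (b.day, joint, BIN_LABELS[k], b.length_class)
            oracle[key] = oracle.get(key, 0) + 1
    for row in df.itertuples(index=False):
        expected = oracle.get((row.day, row.joint, row.bin, row.length_class), 0)
        assert row.dwell_s == pytest.approx(expected / 20.0)
    assert df.dwell_s.sum() * 20.0 == pytest.approx(sum(oracle.values()))


def test_posture_dwell_matches_bruteforce_tally(rng):
    n = 4000
    hip = rng.uniform(0, 180, n)
    knee = rng.uniform(0, 180, n)
    bout_ids = rng.integers(0, 2, n)
    bouts = [_bout(0), _bout(1, prolonged=True)]
    series = _series(hip, knee, bout_ids)
    df = posture_dwell(series, bouts)
    lookup = {b.bout_id: b for b in bouts}
    oracle: dict[tuple, int] = {}
    for i in range(n):
        label = "lying" if hip[i] < 30 else ("bent_sit" if knee[i] >= 45 else "straight_sit")
        b = lookup[int(bout_ids[i])]
        oracle[(b.day, label, b.length_class)] = oracle.get((b.day, label, b.length_class), 0) + 1
    for row in df.itertuples(index=False):
        assert row.dwell_s * 20.0 == pytest.approx(
            oracle.get((row.day, row.posture, row.length_class), 0)
        )


def test_sample_outside_known_bouts_is_a_consistency_error():
    series = _series([50.0], [50.0], [7])
    with pytest.raises(ConsistencyError):
        bin_dwell(series, [_bout(0)])


# ---------------------------------------------------------------------------
# pipeline-level invariants on a rendered day
# ---------------------------------------------------------------------------


def test_dwell_partition_and_additivity(one_day_result):
    """Three postures partition sedentary time; prolonged + non-prolonged =
    total, per posture and per bin; bin totals equal posture totals."""
    res = one_day_result
    fs = res.series.sample_rate
    nondeg_s = float((~res.series.degenerate).sum()) / fs

    posture_total = res.posture_dwell.dwell_s.sum()
    assert posture_total == pytest.approx(nondeg_s, abs=1.0 / fs)
    for joint in ("hip", "knee"):
        joint_total = res.bin_dwell[res.bin_dwell.joint == joint].dwell_s.sum()
        assert joint_total == pytest.approx(nondeg_s, abs=1.0 / fs)

    by_cls = res.posture_dwell.pivot_table(
        index="posture", columns="length_class", values="dwell_s", aggfunc="sum", fill_value=0.0
    )
    totals = res.summary.minutes.sum()
    for posture in by_cls.index:
        total_min = totals[(posture, "total")]
        split_min = (
            by_cls.loc[posture].get("prolonged", 0.0) + by_cls.loc[posture].get("non_prolonged", 0.0)
        ) / 60.0
        assert total_min == pytest.approx(split_min, abs=1e-9)


def test_raising_prolonged_threshold_never_increases_prolonged_dwell(one_day_rendered):
    r = one_day_rendered
    dwell = {}
    for thr in (1800.0, 3600.0, 5400.0):
        bouts = extract_bouts(r.events, r.diary, r.scenario.start, prolonged_threshold_s=thr)
        dwell[thr] = sum(b.duration_s for b in bouts if b.prolonged)
    assert dwell[1800.0] >= dwell[3600.0] >= dwell[5400.0]


def test_events_marked_sedentary_obey_thigh_incline_rule(one_day_scenario):
    """Sedentary events correspond exactly to thigh inclination <= 20 deg."""
    from triposture.synth import events_from_segments

    sc = one_day_scenario
    events = events_from_segments(sc)
    starts = sc.segment_starts_s()
    for ev in events:
        inside = [
            seg
            for s0, seg in zip(starts, sc.segments)
            if s0 >= ev.start_s - 1e-6 and s0 < ev.end_s - 1e-6
        ]
        assert inside
        if ev.activity == "sedentary":
            assert all(s.thigh_incline_deg <= SEDENTARY_INCLINE_MAX_DEG for s in inside)
        else:
            assert all(s.thigh_incline_deg > SEDENTARY_INCLINE_MAX_DEG for s in inside)
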
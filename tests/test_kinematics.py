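"""Dot-product joint angles: closed forms, invariances and geometry."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triposture.activpal_io import AccelTrace, Site
from triposture.errors import CoverageError
from triposture.kinematics import joint_angles, sample_index_range, vector_angle
from triposture.posture import SedentaryBout

ORIGIN = datetime(2023, 1, 2)


def _oracle_angle(a, b):
    """Independent route: atan2 of cross-product magnitude over dot product."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    return np.degrees(np.arctan2(np.linalg.norm(np.cross(a, b), axis=-1), np.sum(a * b, axis=-1)))


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((0, 0, 1), (0, 0, 1), 0.0),
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((2, 0, 0), (1, 1, 0), 45.0),
        ((0, 0, 1), (0, 0, -1), 180.0),
    ],
)
def test_vector_angle_closed_forms(a, b, expected):
    assert vector_angle(a, b) == pytest.approx(expected, abs=1e-9)


def test_vector_angle_matches_high_precision_oracle(rng):
    """1000 random pairs agree with the arctan2 oracle to < 1e-9 degrees."""
    a = rng.normal(size=(1000, 3))
    b = rng.normal(size=(1000, 3))
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    np.testing.assert_allclose(vector_angle(a, b), _oracle_angle(a, b), atol=1e-9)


_vec = st.tuples(
    st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2)
).filter(lambda v: np.linalg.norm(v) >= 0.3)


@settings(derandomize=True, max_examples=100)
@given(a=_vec, b=_vec, k=st.floats(0.1, 5.0))
def test_vector_angle_invariances(a, b, k):
    """Symmetry, positive-scale invariance, self-angle zero, antipodal 180."""
    assert vector_angle(a, b) == pytest.approx(vector_angle(b, a), abs=1e-9)
    # scale invariance is a property of the math; disable the magnitude floor
    # so small k cannot trip the degeneracy flag
    # abs tolerance reflects arccos conditioning (~sqrt(eps)) near 0/180 deg
    assert vector_angle(a, b) == pytest.approx(
        vector_angle(np.multiply(k, a), b, floor_g=0.0), abs=1e-4
    )
    assert vector_angle(a, np.multiply(k, a), floor_g=0.0) == pytest.approx(0.0, abs=1e-3)
    assert vector_angle(a, np.multiply(-1.0, a)) == pytest.approx(180.0, abs=1e-3)


def test_degenerate_magnitudes_are_flagged_not_computed():
    assert np.isnan(vector_angle((0.05, 0, 0), (0, 0, 1)))
    arr = vector_angle(np.array([[0.05, 0, 0], [1, 0, 0]]), np.array([[0, 0, 1], [0, 0, 1]]))
    assert np.isnan(arr[0]) and arr[1] == pytest.approx(90.0)


def test_noise_robustness_of_static_gravity_angles(rng):
    """Isotropic 0.05 g noise on a static 1 g gravity vector perturbs the
    measured inter-segment angle by < 3 deg RMS (~ 0.05 rad of transverse
    direction error; both-vectors-noisy scales this by sqrt(2))."""
    n = 20000
    a = np.tile([1.0, 0.0, 0.0], (n, 1)) + rng.normal(0, 0.05, (n, 3))
    b = np.tile([0.0, 0.0, 1.0], (n, 1))
    err = vector_angle(a, b) - 90.0
    assert np.sqrt(np.mean(err**2)) < 3.0
    both = vector_angle(a, b + rng.normal(0, 0.05, (n, 3))) - 90.0
    assert np.sqrt(np.mean(both**2)) < 3.0 * np.sqrt(2.0)


def test_sample_index_range_is_half_open_on_the_grid():
    assert sample_index_range(0.0, 1.0, 20.0) == (0, 20)
    assert sample_index_range(0.05, 0.1, 20.0) == (1, 2)
    assert sample_index_range(0.025, 0.1, 20.0) == (1, 2)  # first sample at/after start


def _static_traces(torso_vec, thigh_vec, shin_vec, n=200):
    def mk(site, v):
        return AccelTrace(site=site, start=ORIGIN, samples=np.tile(v, (n, 1)), sample_rate=20.0)

    return mk(Site.TORSO, torso_vec), mk(Site.THIGH, thigh_vec), mk(Site.SHIN, shin_vec)


def _bout(start_s, duration_s, bout_id=0):
    return SedentaryBout(
        bout_id=bout_id,
        start_s=start_s,
        duration_s=duration_s,
        day=ORIGIN.date(),
        prolonged=False,
        clipped=False,
    )


def test_joint_angles_static_sitting_geometry():
    """Torso vertical, thigh horizontal, shin vertical -> hip 90, knee 90."""
    torso, thigh, shin = _static_traces([0, 0, 1.0], [1.0, 0, 0], [0, 0, 1.0])
    series = joint_angles(torso, thigh, shin, [_bout(0.0, 5.0)])
    assert series.n_samples == 100
    np.testing.assert_allclose(series.hip_deg, 90.0, atol=1e-9)
    np.testing.assert_allclose(series.knee_deg, 90.0, atol=1e-9)
    assert np.all(series.bout_id == 0)


def test_joint_angles_static_lying_geometry():
    """All three monitors horizontal, same direction -> hip 0, knee 0."""
    torso, thigh, shin = _static_traces([1.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0])
    series = joint_angles(torso, thigh, shin, [_bout(0.0, 5.0)])
    np.testing.assert_allclose(series.hip_deg, 0.0, atol=1e-9)
    np.testing.assert_allclose(series.knee_deg, 0.0, atol=1e-9)


def test_joint_angles_flags_degenerate_samples_without_dropping():
    torso, thigh, shin = _static_traces([0, 0, 1.0], [1.0, 0, 0], [0, 0, 1.0])
    thigh.samples[10] = [0.01, 0.0, 0.0]  # transient: magnitude below the floor
    series = joint_angles(torso, thigh, shin, [_bout(0.0, 5.0)])
    assert series.n_samples == 100  # flagged, not removed
    assert series.degenerate.sum() == 1
    assert np.isnan(series.hip_deg[10]) and np.isnan(series.knee_deg[10])


def test_bout_outside_trace_span_is_a_coverage_error():
    torso, thigh, shin = _static_traces([0, 0, 1.0], [1.0, 0, 0], [0, 0, 1.0])
    with pytest.raises(CoverageError):
        joint_angles(torso, thigh, shin, [_bout(5.0, 10.0)])


def test_rendered_scenario_angles_match_ground_truth_segments():
    """Noiseless, unquantized rendering reproduces the scheduled hip/knee
    angles to 0.1 deg away from segment transitions (filter settling)."""
    from triposture.cli import analyze_traces
    from triposture.synth import make_scenario, render

    sc = make_scenario(seed=21, days=1, noise_sd_g=0.0, jitter_sd_deg=0.0, sample_rate=2.0)
    r = render(sc, quantize=False)
    result = analyze_traces(r.torso, r.thigh, r.shin, r.events, r.diary)
    series = result.series

    starts = sc.segment_starts_s()
    margin = 15.0  # seconds: > 5 filter time constants on each side
    expect_hip = np.full(series.n_samples, np.nan)
    expect_knee = np.full(series.n_samples, np.nan)
    for s0, seg in zip(starts, sc.segments):
        inside = (series.times_s >= s0 + margin) & (series.times_s < s0 + seg.duration_s - margin)
        expect_hip[inside] = seg.hip_deg
        expect_knee[inside] = seg.knee_deg
    keep = ~np.isnan(expect_hip)
    assert keep.sum() > 1000
    np.testing.assert_allclose(series.hip_deg[keep], expect_hip[keep], atol=0.1)
    np.testing.assert_allclose(series.knee_deg[keep], expect_knee[keep], atol=0.1)


def test_quantized_rendering_angle_error_is_bounded():
    """8-bit AP3 quantization alone keeps interior angle errors within 1 deg."""
    from triposture.cli import analyze_traces
    from triposture.synth import make_scenario, render

    sc = make_scenario(seed=21, days=1, noise_sd_g=0.0, jitter_sd_deg=0.0, sample_rate=2.0)
    r = render(sc, quantize=True)
    result = analyze_traces(r.torso, r.thigh, r.shin, r.events, r.diary)
    series = result.series

    starts = sc.segment_starts_s()
    margin = 15.0
    expect_hip = np.full(series.n_samples, np.nan)
    for s0, seg in zip(starts, sc.segments):
        inside = (series.times_s >= s0 + margin) & (series.times_s < s0 + seg.duration_s - margin)
        expect_hip[inside] = seg.hip_deg
    keep = ~np.isnan(expect_hip)
    assert np.max(np.abs(series.hip_deg[keep] - expect_hip[keep])) < 1.0
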
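"""Hip and knee flexion angles by the gravity-vector dot-product method.

During sedentary time each monitor's low-pass-filtered signal approximates the
unit gravity vector in its local frame.  With the torso, thigh and shin
monitors mounted anteriorly and mutually parallel, the angle between two
monitors' gravity vectors equals the inter-segment flexion angle relative to
upright anatomical position (standing -> hip ~ 0 deg, knee ~ 0 deg):

    angle = arccos( (a . b) / (|a| |b|) )

Hip flexion is the torso-thigh angle and knee flexion the thigh-shin angle,
evaluated per sample within sedentary bouts only.  Samples where any monitor's
vector magnitude falls below a floor (movement transients) are flagged
degenerate (NaN angles) rather than dropped, and are excluded from downstream
dwell tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .activpal_io import AccelTrace
from .errors import AlignmentError, CoverageError

if TYPE_CHECKING:  # pragma: no cover
    from .posture import SedentaryBout

__all__ = [
    "DEFAULT_MAGNITUDE_FLOOR_G",
    "vector_angle",
    "sample_index_range",
    "JointAngleSeries",
    "joint_angles",
]

#: below this vector magnitude the gravity direction is unreliable
DEFAULT_MAGNITUDE_FLOOR_G = 0.2


def vector_angle(a, b, floor_g: float = DEFAULT_MAGNITUDE_FLOOR_G):
    """Angle in degrees between triaxial vectors ``a`` and ``b``.

    Accepts single vectors or ``(..., 3)`` stacks.  The arccos argument is
    clamped to [-1, 1]; the result is symmetric in its arguments and invariant
    to positive scaling of either.  Pairs where either magnitude is below
    *floor_g* yield NaN (degenerate flag).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    scalar = a.ndim == 1 and b.ndim == 1
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    denom = na * nb
    with np.errstate(divide="ignore", invalid="ignore"):
        cosv = np.sum(a * b, axis=-1) / denom
    ang = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
    ang = np.where((na < floor_g) | (nb < floor_g), np.nan, ang)
    return float(ang) if scalar else ang


def sample_index_range(start_s: float, end_s: float, sample_rate: float) -> tuple[int, int]:
    """Indices of samples falling in the half-open interval [start_s, end_s).

    Sample ``i`` occurs at ``i / sample_rate``; returns ``(i0, i1)`` with the
    samples being ``i0 .. i1 - 1``.  A small guard absorbs float rounding so
    interval ends on the sample grid behave exactly half-open.
    """
    i0 = int(math.ceil(start_s * sample_rate - 1e-6))
    i1 = int(math.ceil(end_s * sample_rate - 1e-6))
    return i0, i1


@dataclass
class JointAngleSeries:
    """Per-sample hip and knee flexion angles during sedentary bouts.

    ``hip``/``knee`` are degrees in [0, 180] with NaN marking degenerate
    samples; ``bout_id`` maps every sample to its enclosing sedentary bout.
    """

    times_s: np.ndarray
    hip_deg: np.ndarray
    knee_deg: np.ndarray
    bout_id: np.ndarray
    sample_rate: float

    @property
    def n_samples(self) -> int:
        return int(self.times_s.shape[0])

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of samples excluded from dwell tallies."""
        return np.isnan(self.hip_deg) | np.isnan(self.knee_deg)


def joint_angles(
    torso: AccelTrace,
    thigh: AccelTrace,
    shin: AccelTrace,
    bouts: Sequence["SedentaryBout"],
    floor_g: float = DEFAULT_MAGNITUDE_FLOOR_G,
) -> JointAngleSeries:
    """Hip (torso-thigh) and knee (thigh-shin) angles inside sedentary bouts.

    The traces must already be aligned (same start, rate and length); bout
    times are seconds since the shared trace start.  A sample is degenerate if
    *any* of the three monitor vectors falls below *floor_g*, so hip and knee
    tallies stay defined on the same sample set.
    """
    traces = (torso, thigh, shin)
    if len({t.n_samples for t in traces}) != 1 or len({t.sample_rate for t in traces}) != 1:
        raise AlignmentError("traces are not aligned: differing lengths or rates")
    if len({t.start for t in traces}) != 1:
        raise AlignmentError("traces are not aligned: differing starts")
    fs = torso.sample_rate
    n = torso.n_samples

    idx_parts: list[np.ndarray] = []
    bout_parts: list[np.ndarray] = []
    for bout in bouts:
        i0, i1 = sample_index_range(bout.start_s, bout.end_s, fs)
        if i0 < 0 or i1 > n:
            raise CoverageError(
                f"bout {bout.bout_id} [{bout.start_s}, {bout.end_s}) s outside the "
                f"trace span of {n / fs} s"
            )
        idx_parts.append(np.arange(i0, i1, dtype=np.int64))
        bout_parts.append(np.full(i1 - i0, bout.bout_id, dtype=np.int64))

    idx = np.concatenate(idx_parts) if idx_parts else np.empty(0, dtype=np.int64)
    bout_ids = np.concatenate(bout_parts) if bout_parts else np.empty(0, dtype=np.int64)

    hip = vector_angle(torso.samples[idx], thigh.samples[idx], floor_g=floor_g)
    knee = vector_angle(thigh.samples[idx], shin.samples[idx], floor_g=floor_g)
    # degenerate anywhere -> degenerate everywhere (common sample set)
    bad = np.isnan(hip) | np.isnan(knee)
    hip = np.where(bad, np.nan, hip)
    knee = np.where(bad, np.nan, knee)

    return JointAngleSeries(
        times_s=idx.astype(np.float64) / fs,
        hip_deg=hip,
        knee_deg=knee,
        bout_id=bout_ids,
        sample_rate=fs,
    )
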
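# Methods

## Signal model and assumptions

Each monitor is treated as an inclinometer: during quasi-static postures its
triaxial output is the unit gravity vector expressed in the monitor's local
frame, plus sensor noise and movement accelerations. With the three monitors
mounted anteriorly and mutually parallel (right anterior thigh, anteromedial
tibia, right torso below the ribcage), the angle between two monitors'
gravity vectors equals the inter-segment flexion angle relative to upright
anatomical position, so no mounting calibration is required in the ideal
case. The model is insensitive to rotations about the long (superior–
inferior) axis; postures where gravity acts mainly medio-laterally
(cross-legged sitting, side-lying) are outside its validity — a known
limitation of the dot-product approach, not corrected here.

An optional standing-calibration hook exists conceptually (subtract the
median angle over upright time as a strap-misalignment offset) but is off by
default: it changes the estimand, and the synthetic studies here mount the
virtual monitors perfectly.

## Filtering

Gravity is isolated with a 1st-order digital Butterworth low-pass at
0.18 Hz, realized by `scipy.signal.butter` + `filtfilt` (forward–backward,
hence zero net phase and a squared single-pass magnitude). Edge transients
are handled with reflective (`even`) padding of at least three filter time
constants (τ = 1/(2π·0.18) ≈ 0.88 s → 53 samples at 20 Hz); traces shorter
than the pad are rejected. Whole recordings are filtered once, before bout
extraction, so bout-edge samples are not re-transient.

One numerical point deserves care: the closed-form magnitude of the
**digital** (bilinear) filter is `|H(f)|² = 1/(1 + (tan(πf/fs)/tan(πfc/fs))²)`
per pass. The familiar analog form `1/(1+(f/fc)²)` is its f ≪ fs limit and
is already ~60 % off at f = 5 Hz with fs = 20 Hz; tests therefore check the
measured sinusoid attenuation against the digital closed form (with
`freqz` as an independent oracle) and check the analog form only in the
low-frequency regime where it applies.

## Angles, degeneracy and boundary conventions

`vector_angle` clamps the normalized dot product to [−1, 1] before arccos.
Samples where any monitor's vector magnitude falls below 0.2 g (movement
transients; gravity direction unreliable) are flagged degenerate — NaN in
the series, excluded from every dwell tally, reported as a per-day QC
fraction — rather than silently dropped. A sample degenerate for either
joint is degenerate for both, so hip and knee tallies cover the identical
sample set and conservation checks are exact.

Thresholds use strict inequalities on the open sides and deterministic
conventions at equality (measure-zero in practice): hip = 30° → sitting,
knee = 45° → bent-knee; 15° bins are lower-closed with the last bin
spanning [75°, 180°]. Prolonged means strictly > 3600 s of *clipped waking*
duration. Posture is classified per sample, not per bout, so one bout can
split across labels and bins — the only reading under which a single event
can populate several bins of the dwell table.

## Bout extraction and day accounting

Sedentary events from the thigh events file are intersected with the
diary's half-open waking windows [wake, sleep); a sleep time at or before
the wake time denotes sleep onset past midnight. Events wholly inside sleep
are dropped; partial overlaps are clipped and flagged. Every diary day is a
valid day (no minimum wear-hours filter by default — the target use case is
24 h/day wear); days without prolonged bouts contribute zeros to prolonged
averages, and rounding to 0.1 min happens only at presentation so
total = prolonged + non-prolonged holds exactly internally.

## Statistics

Participant-level means feed Shapiro–Wilk checks per variable and two-sided
Wilcoxon signed-rank tests: the three pairwise posture contrasts on total
min/day at the Bonferroni-adjusted threshold α = 0.05/3 (kept unrounded
internally; printed as 0.017), plus prolonged-vs-non-prolonged within each
posture. Zero differences are dropped (standard signed-rank treatment); the
exact null is used for ≤ 25 informative pairs, otherwise the normal
approximation with continuity correction; ties force the approximation. An
all-zero difference vector is reported as undefined rather than given a
p-value.

## Synthetic scenarios

The generator emulates the three vendor file kinds with known truth. Default
conditions: 16 h waking days (07:00–23:00), bent-knee sitting 439,
straight-legged sitting 113, lying 69 min/day, one third of each posture's
time in prolonged bouts (65–110 min), the rest in short bouts of
8.8 ± 1.8 min, separated by ≥ 1 min upright gaps; state angles
(hip, knee, incline) are (10°, 10°, 0°) lying, (90°, 90°, 0°) bent,
(90°, 20°, 0°) straight, (0°, 0°, 90°) upright — each ≥ 5° from every bin
edge and ≥ 10° from every posture threshold, so noise of realistic size
cannot flip labels. Bouts are planned at the week level because a posture's
prolonged share can be under one bout-hour per day (e.g. lying): some days
get a > 1 h bout, others none, which naturally exercises the zero-filling
rule. Noise: isotropic Gaussian (default 0.02 g, 0.05 g in stress tests)
plus slow per-monitor angular wander (60 s control points, default 2° SD),
then quantization through the inverse count map (AP3 LSB = 1/63 g), so file
round-trips are bit-exact.

Ground truth is computed analytically from the segments on the sample grid
(sample i at i/fs; intervals half-open), with its own independent
event/waking-window intersection — never by rendering.

What the generator does **not** emulate: movement-acceleration bursts and
postural adjustments within sedentary bouts, long-axis rotations,
strap-mounting offsets, sensor drift, gait. Passing recovery tests
therefore demonstrates correctness of the pipeline's arithmetic and logic
under the stated signal model, not field accuracy of the angle estimates on
real recordings (reported elsewhere as ~5–10° MAE against motion capture).

Two tolerance subtleties: (i) per-sample angle agreement to 0.1° is only
meaningful away from segment transitions (the 0.18 Hz filter needs ~10–15 s
to settle) and without quantization (8-bit AP3 quantization alone biases a
static angle by up to ~0.6°, bounded at 1° in tests); (ii) posture *dwell*
recovery is unaffected by both effects because the scheduled angles sit far
from thresholds and transition blending between a sedentary posture and the
upright reference crosses no threshold on the bout-interior side.

## Problem sizes and determinism

Recovery studies use 7-day single-participant scenarios at 20 Hz
(~12.1 M samples per monitor) — the scale of one real wear period — and
file-level round-trip tests use a 2 Hz day to keep CSVs small; the
cohort-statistics study uses 20 participants × 200 seeded replicates. All
randomness flows from explicit seeds (`numpy.random.default_rng`); renders,
analyses and CLI outputs are deterministic, and reruns of `analyze` on the
same inputs are byte-identical.
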
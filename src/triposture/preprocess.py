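"""Gravity-component extraction and tri-monitor clock alignment.

The quasi-static gravity vector is isolated with a 1st-order zero-lag digital
Butterworth low-pass at a 0.18 Hz cut-off: the filter is applied forward and
backward (``scipy.signal.filtfilt``) so the net phase shift is zero and the
effective magnitude response is squared.  Edge transients are suppressed with
reflective padding of at least three filter time constants.

Filtering is applied to full recordings once, before bout extraction, so
bout-edge samples are not re-transient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from scipy import signal

from .activpal_io import AccelTrace
from .errors import AlignmentError, ConfigurationError, InputTooShortError

logger = logging.getLogger(__name__)

__all__ = ["FilterSpec", "lowpass", "align", "two_pass_gain"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter parameters (zero-lag is inherent: two-pass application)."""

    cutoff_hz: float = 0.18
    order: int = 1

    def validate(self, sample_rate: float) -> None:
        if not 0 < self.cutoff_hz < sample_rate / 2:
            raise ConfigurationError(
                f"cutoff {self.cutoff_hz} Hz outside (0, {sample_rate / 2}) Hz"
            )
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")

    def pad_samples(self, sample_rate: float) -> int:
        """Reflective pad length: >= 3 time constants (tau = 1/(2 pi fc))."""
        tau_s = 1.0 / (2.0 * math.pi * self.cutoff_hz)
        return max(int(math.ceil(3.0 * tau_s * sample_rate)), 3 * (self.order + 1))


def lowpass(trace: AccelTrace, spec: FilterSpec | None = None) -> AccelTrace:
    """Zero-lag Butterworth low-pass of each axis; DC gain 1, length preserved."""
    spec = spec or FilterSpec()
    spec.validate(trace.sample_rate)
    padlen = spec.pad_samples(trace.sample_rate)
    if trace.n_samples <= padlen:
        raise InputTooShortError(
            f"trace of {trace.n_samples} samples shorter than filter warm-up "
            f"({padlen} samples)"
        )
    b, a = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=trace.sample_rate)
    filtered = signal.filtfilt(b, a, trace.samples, axis=0, padtype="even", padlen=padlen)
    return replace(trace, samples=filtered)


def two_pass_gain(freq_hz: float, spec: FilterSpec | None = None, sample_rate: float = 20.0) -> float:
    """Closed-form squared-magnitude response |H(f)|^2 of the two-pass filter.

    For the order-1 digital (bilinear) Butterworth,
    ``|H(f)|^2 = 1 / (1 + (tan(pi f/fs) / tan(pi fc/fs))**order * ... )`` with
    the frequency axis pre-warped by the tangent map; the two-pass (forward +
    backward) application squares the single-pass magnitude.  In the
    low-frequency regime (f << fs) this reduces to the analog form
    ``1 / (1 + (f/fc)**(2*order))``.
    """
    spec = spec or FilterSpec()
    warped = math.tan(math.pi * freq_hz / sample_rate) / math.tan(
        math.pi * spec.cutoff_hz / sample_rate
    )
    single_pass_sq = 1.0 / (1.0 + warped ** (2 * spec.order))
    return single_pass_sq  # |H|^2: squared magnitude == two-pass amplitude gain


def align(
    torso: AccelTrace, thigh: AccelTrace, shin: AccelTrace
) -> tuple[AccelTrace, AccelTrace, AccelTrace]:
    """Place the three monitor traces on a shared sample index.

    Requires identical sample rates and starts within one sample period of
    each other; traces are truncated to the shortest common length (never
    reordered or interpolated).
    """
    traces = (torso, thigh, shin)
    rates = {t.sample_rate for t in traces}
    if len(rates) != 1:
        raise ConfigurationError(f"differing sample rates: {sorted(rates)}")
    fs = torso.sample_rate
    ref = torso.start
    for t in traces:
        if abs((t.start - ref).total_seconds()) > 1.0 / fs:
            raise AlignmentError(
                f"{t.site.value} start {t.start} differs from {ref} by more than "
                f"one sample period"
            )
    n = min(t.n_samples for t in traces)
    dropped = sum(t.n_samples - n for t in traces)
    if dropped:
        logger.warning("align: dropped %d trailing samples to common length %d", dropped, n)
    return tuple(
        replace(t, samples=t.samples[:n]) if t.n_samples != n else t for t in traces
    )  # type: ignore[return-value]
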
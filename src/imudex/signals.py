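"""Scalar signals derived from a sensor stream.

The pipeline works on magnitude signals rather than individual axes: the
angular-speed magnitude S_omega = sqrt(gx^2 + gy^2 + gz^2) (deg/s) and the
gravity-compensated acceleration magnitude S_a = |a| - g (m/s^2). Activity
detection and movement counting run on the Hilbert envelope of S_omega,
smoothed with a short Hann window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .io import SensorStream, ValidationError

KINDS = ("angular_speed_Somega", "accel_Sa", "speed_Va", "envelope",
         "gyro_axis")


@dataclass
class MagnitudeSeries:
    """A scalar series on the stream's uniform time grid."""

    t: np.ndarray
    values: np.ndarray
    kind: str
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValidationError("t and values must have the same length")
        if self.kind not in KINDS:
            raise ValidationError(f"unknown series kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("series contains non-finite values")

    def __len__(self) -> int:
        return len(self.t)

    def with_values(self, values: np.ndarray,
                    kind: str | None = None) -> "MagnitudeSeries":
        return MagnitudeSeries(self.t, values, kind or self.kind, self.fs)

    def index_of(self, t: float) -> int:
        """Index of the first sample at or after time t."""
        return int(np.searchsorted(self.t, t, side="left"))

    def index_after(self, t: float) -> int:
        """Index one past the last sample at or before time t, so a
        slice [index_of(t0):index_after(t1)] includes a sample landing
        exactly on t1 (integration endpoints are inclusive)."""
        return int(np.searchsorted(self.t, t, side="right"))


def angular_speed_magnitude(stream: SensorStream) -> MagnitudeSeries:
    """Euclidean magnitude of the three gyroscope channels (deg/s)."""
    return MagnitudeSeries(
        stream.t, np.linalg.norm(stream.gyr, axis=1),
        "angular_speed_Somega", stream.fs)


def accel_magnitude(stream: SensorStream, g: float) -> MagnitudeSeries:
    """|a| - g: accelerometer magnitude with gravity magnitude removed.

    This compensates gravity only approximately (it ignores orientation),
    but it is exact for a stationary sensor and needs no attitude estimate;
    the result may be negative (e.g. in free fall).
    """
    return MagnitudeSeries(
        stream.t, np.linalg.norm(stream.acc, axis=1) - g,
        "accel_Sa", stream.fs)


def hilbert_envelope(x: MagnitudeSeries) -> MagnitudeSeries:
    """Modulus of the analytic signal of x.

    For an oscillatory signal this outlines the peaks and removes most
    zero crossings, which is what makes a simple threshold comparator on
    it a robust activity detector.
    """
    if len(x) < 4:
        raise ValidationError("need at least 4 samples for an envelope")
    return x.with_values(np.abs(hilbert(x.values)), "envelope")


def hanning_smooth(x: MagnitudeSeries, window_ms: float) -> MagnitudeSeries:
    """Zero-phase FIR smoothing with a unit-sum Hann window.

    The window length is round(window_ms * fs / 1000) samples, forced odd
    so the symmetric filter is centered and peak times are not delayed.
    Edges use reflection padding; constant signals are fixed points.
    """
    n_win = int(round(window_ms * x.fs / 1000.0))
    if n_win % 2 == 0:
        n_win += 1
    if n_win < 3:
        raise ValidationError("smoothing window must span >= 3 samples")
    if n_win > len(x):
        raise ValidationError("smoothing window longer than the signal")
    w = np.hanning(n_win + 2)[1:-1]  # strictly positive interior taps
    w /= w.sum()
    half = n_win // 2
    padded = np.pad(x.values, half, mode="reflect")
    return x.with_values(np.convolve(padded, w, mode="valid"))


def detrend_somega(x: MagnitudeSeries, mode: str = "rest_baseline",
                   rest_intervals=None) -> MagnitudeSeries:
    """Remove gyroscope drift from an angular-speed magnitude.

    ``rest_baseline`` subtracts the mean of x over the given rest
    intervals (the sensor's noise floor while the hand is still) and
    clamps at zero, preserving the area of genuine rotation. ``linear``
    subtracts the least-squares line; it is kept for fidelity experiments
    but can produce negative values and remove constant rotation.
    """
    if mode == "rest_baseline":
        if not rest_intervals:
            raise ValidationError(
                "rest_baseline detrend requires rest intervals")
        mask = np.zeros(len(x), dtype=bool)
        for iv in rest_intervals:
            t0, t1 = (iv.t_ini, iv.t_end) if hasattr(iv, "t_ini") else iv
            mask |= (x.t >= t0) & (x.t < t1)
        if not mask.any():
            raise ValidationError("rest intervals contain no samples")
        baseline = float(x.values[mask].mean())
        return x.with_values(np.maximum(x.values - baseline, 0.0))
    if mode == "linear":
        coeffs = np.polyfit(x.t, x.values, 1)
        return x.with_values(x.values - np.polyval(coeffs, x.t))
    raise ValidationError(f"unknown detrend mode {mode!r}")
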
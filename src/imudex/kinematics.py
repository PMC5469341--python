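"""Displacement metrics by numerical integration of magnitude signals.

Two path-length metrics are computed per exercise: the total angular path
Disp_theta (deg), the trapezoidal area under the detrended angular-speed
magnitude, and the total spatial path Disp (m), the trapezoidal area under
|Va|, where the speed magnitude Va solves dVa/dt = S_a with a fixed-step
4th-order Runge-Kutta integrator run movement-by-movement with chained
initial conditions (Va = 0 at exercise onset, each movement starting at
the previous movement's final speed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .io import Recording, ValidationError, calibrate_offsets
from .movements import (MovementSegment, detect_movement_peaks,
                        epochs_from_peaks, movements_metric)
from .segmentation import (ExerciseInterval, rest_intervals,
                           segment_exercises)
from .signals import (MagnitudeSeries, accel_magnitude,
                      angular_speed_magnitude, detrend_somega)


@dataclass(frozen=True)
class MetricsRecord:
    """Dexterity metrics of one subject x exercise x sensor."""

    subject: str
    exercise: int
    sensor: int
    duration: float
    movements: int
    disp: float
    disp_theta: float

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.movements < 0 or self.disp < 0 \
                or self.disp_theta < 0:
            raise ValidationError("metric out of range")


@dataclass
class KinematicResult:
    """Displacement metrics plus the intermediate speed series."""

    disp_theta: float
    disp: float
    va_series: MagnitudeSeries
    per_segment: list[tuple[int, float]] = field(default_factory=list)


def angular_displacement(somega: MagnitudeSeries,
                         interval: ExerciseInterval,
                         config: PipelineConfig | None = None,
                         rest: list | None = None) -> float:
    """Total angular path (deg): trapezoidal area of detrended S_omega
    over the exercise.

    ``rest`` gives the rest intervals used by the rest-baseline detrend;
    when omitted, the part of the series outside the exercise is used,
    and a series with no outside samples is integrated as-is.
    """
    config = config or PipelineConfig()
    i0, i1 = somega.index_of(interval.t_ini), somega.index_of(interval.t_end)
    if i0 >= i1 or i1 > len(somega):
        raise ValidationError("interval outside the series")
    if config.detrend_mode == "rest_baseline":
        if rest is None:
            rest = rest_intervals([interval], somega.t[0],
                                  somega.t[-1] + 1.0 / somega.fs)
        detrended = (detrend_somega(somega, "rest_baseline", rest)
                     if rest else somega)
    else:
        detrended = detrend_somega(somega, "linear")
    return float(np.trapezoid(detrended.values[i0:i1], somega.t[i0:i1]))


def segmentation_signal(stream, axis: int | None = 2) -> MagnitudeSeries:
    """The series fed to the exercise segmenter.

    By default a single signed gyro axis (z): real hand motion reverses
    direction, so a single-axis trace oscillates around zero and its
    Hilbert envelope localizes activity sharply. The non-negative
    magnitude S_omega carries a large DC component whose envelope skirts
    extend seconds past the activity edges; pass ``axis=None`` to use it
    anyway.
    """
    from .signals import angular_speed_magnitude
    if axis is None:
        return angular_speed_magnitude(stream)
    return MagnitudeSeries(stream.t, stream.gyr[:, axis], "gyro_axis",
                           stream.fs)


def _check_tiling(segments: list[MovementSegment], tol: float) -> None:
    for prev, nxt in zip(segments, segments[1:]):
        if abs(nxt.t_start - prev.t_end) > tol:
            raise ValidationError("movement segments must tile the exercise")


def integrate_velocity(sa: MagnitudeSeries,
                       segments: list[MovementSegment],
                       config: PipelineConfig | None = None
                       ) -> MagnitudeSeries:
    """Speed magnitude Va from dVa/dt = S_a by fixed-step RK4.

    The step is the sample period; S_a is interpolated linearly at half
    steps. Integration runs movement-by-movement: Va = 0 at the start of
    the first segment and each later segment starts from the previous
    segment's final value, so Va is continuous across the exercise.
    """
    config = config or PipelineConfig()
    if not segments:
        raise ValidationError("no movement segments")
    _check_tiling(segments, 1.0 / sa.fs)
    t0, t1 = segments[0].t_start, segments[-1].t_end
    i0, i1 = sa.index_of(t0), sa.index_after(t1)
    if i1 - i0 < 2:
        raise ValidationError("exercise must contain at least 2 samples")
    t = sa.t[i0:i1]
    y = sa.values[i0:i1]
    half = 0.5 * (y[:-1] + y[1:])  # linear interpolation at half steps
    dt = np.diff(t)
    # RK4 for dv/dt = f(t): k1=y_n, k2=k3=y_{n+1/2}, k4=y_{n+1}
    increments = dt / 6.0 * (y[:-1] + 4.0 * half + y[1:])
    va = np.concatenate(([0.0], np.cumsum(increments)))
    return MagnitudeSeries(t, va, "speed_Va", sa.fs)


def anchor_zero_velocity(va: MagnitudeSeries,
                         segments: list[MovementSegment]
                         ) -> MagnitudeSeries:
    """Zero-velocity update at movement boundaries.

    Voluntary movements start and end with the hand (near) still, so Va
    should return to ~0 at every movement boundary; any residual there
    is accumulated integration drift (offset and noise random walk).
    The correction subtracts the piecewise-linear interpolant through
    Va's values at the boundaries, pinning them to zero while leaving
    within-movement dynamics intact.
    """
    anchors_t = [segments[0].t_start] + [s.t_end for s in segments]
    idx = np.clip([va.index_of(a) for a in anchors_t], 0, len(va) - 1)
    drift = np.interp(va.t, va.t[idx], va.values[idx])
    return va.with_values(va.values - drift)


def spatial_displacement(va: MagnitudeSeries,
                         interval: ExerciseInterval) -> float:
    """Total spatial path (m): trapezoidal area of |Va| over the exercise.

    The absolute value is what makes this a path length rather than a net
    displacement (which would integrate to ~0)."""
    i0, i1 = va.index_of(interval.t_ini), va.index_after(interval.t_end)
    i1 = min(i1, len(va))
    return float(np.trapezoid(np.abs(va.values[i0:i1]), va.t[i0:i1]))


def _per_segment_disp(va: MagnitudeSeries,
                      segments: list[MovementSegment]) -> list[tuple[int, float]]:
    return [(seg.index,
             spatial_displacement(va, ExerciseInterval(seg.t_start,
                                                       seg.t_end)))
            for seg in segments]


def kinematics_for_interval(somega: MagnitudeSeries, sa: MagnitudeSeries,
                            interval: ExerciseInterval,
                            config: PipelineConfig,
                            rest: list | None = None) -> KinematicResult:
    """Disp_theta, Va and Disp for one sensor over one exercise."""
    peaks = detect_movement_peaks(somega, interval, config)
    segments = epochs_from_peaks(peaks, interval)
    va = integrate_velocity(sa, segments, config)
    if config.va_zero_anchor:
        va = anchor_zero_velocity(va, segments)
    return KinematicResult(
        disp_theta=angular_displacement(somega, interval, config, rest),
        disp=spatial_displacement(va, interval),
        va_series=va,
        per_segment=_per_segment_disp(va, segments))


def compute_metrics(rec: Recording,
                    config: PipelineConfig | None = None,
                    reference_sensor: int | None = None,
                    calibrate: bool = True) -> list[MetricsRecord]:
    """Run the full metric pipeline on a recording.

    Exercises are segmented once, on a single gyro axis (z) of the
    reference sensor (the back-of-hand sensor by default), and the same
    intervals are applied to every sensor — the sensors share the hand's
    activity schedule even where their signals differ in detail. A
    signed single-axis signal is used because the Hilbert envelope of
    the non-negative magnitude S_omega has long skirts that smear
    activity edges; see :func:`segmentation_signal`. When a
    leading rest period of at least 0.5 s precedes the first exercise it
    is used to calibrate static offsets before the metrics are computed.
    Returns one :class:`MetricsRecord` per sensor x exercise; an all-rest
    recording yields an empty list.
    """
    config = config or PipelineConfig()
    ref = reference_sensor if reference_sensor is not None \
        else rec.sensor_ids[0]
    ref_stream = rec.streams[ref]
    intervals = segment_exercises(segmentation_signal(ref_stream), config)
    if not intervals:
        return []

    t_lo = ref_stream.t[0]
    t_hi = ref_stream.t[-1] + 1.0 / config.fs
    streams = rec.streams
    if calibrate and intervals[0].t_ini - t_lo >= 0.5:
        window = (t_lo, intervals[0].t_ini)
        # gyro-bias removal only: the accel rescale's estimation error
        # integrates into speed drift and outweighs its benefit here
        streams = {sid: calibrate_offsets(s, window, config.g,
                                          rescale_accel=False)
                   for sid, s in streams.items()}
        intervals = segment_exercises(
            segmentation_signal(streams[ref]), config)
        if not intervals:
            return []
    rest = rest_intervals(intervals, t_lo, t_hi)

    records = []
    for sid in sorted(streams):
        stream = streams[sid]
        somega = angular_speed_magnitude(stream)
        sa = accel_magnitude(stream, config.g)
        for iv in intervals:
            peaks = detect_movement_peaks(somega, iv, config)
            kin = kinematics_for_interval(somega, sa, iv, config, rest)
            records.append(MetricsRecord(
                subject=rec.subject_id, exercise=iv.index + 1, sensor=sid,
                duration=iv.duration, movements=movements_metric(peaks),
                disp=kin.disp, disp_theta=kin.disp_theta))
    return records
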
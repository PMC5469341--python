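"""Activity detection: split a recording into exercises and rest.

Subjects rest their hand on the table between exercises, so activity
periods are found by comparing the Hilbert envelope of an angular-speed
signal against a fixed threshold (15 deg/s by default), followed by a
two-step cleanup: supra-threshold runs of one second or less are discarded
as false positives, then sub-threshold holes of up to one second inside
activity are filled. The Duration metric of an exercise is t_end - t_ini.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .io import ValidationError
from .signals import MagnitudeSeries, hilbert_envelope


@dataclass(frozen=True)
class ExerciseInterval:
    """Half-open activity window [t_ini, t_end), ordinal within a recording."""

    t_ini: float
    t_end: float
    index: int = 0

    def __post_init__(self) -> None:
        if not self.t_end > self.t_ini:
            raise ValidationError("t_end must exceed t_ini")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_ini


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def segment_exercises(signal: MagnitudeSeries,
                      config: PipelineConfig | None = None
                      ) -> list[ExerciseInterval]:
    """Detect exercise intervals from an angular-speed (or single-axis
    gyro) series.

    The comparator is ON where the Hilbert envelope exceeds
    ``config.exercise_threshold``; ON runs no longer than
    ``config.min_event_s`` are removed first, then OFF holes no longer
    than ``config.hole_fill_s`` between surviving ON runs are filled.
    Interval endpoints are the times of the first sample of the run and
    one sample past its last (half-open).
    """
    config = config or PipelineConfig()
    if len(signal) == 0:
        raise ValidationError("empty signal")
    env = hilbert_envelope(signal)
    on = env.values > config.exercise_threshold
    dt = 1.0 / signal.fs

    # 1) drop short ON runs (false positives from involuntary movement)
    min_len = int(round(config.min_event_s * signal.fs))
    for i0, i1 in _runs(on):
        if i1 - i0 <= min_len:
            on[i0:i1] = False
    # 2) fill short OFF holes between remaining ON runs
    hole_len = int(round(config.hole_fill_s * signal.fs))
    off_runs = _runs(~on)
    for i0, i1 in off_runs:
        interior = i0 > 0 and i1 < len(on)
        if interior and i1 - i0 <= hole_len:
            on[i0:i1] = True

    intervals = []
    for k, (i0, i1) in enumerate(_runs(on)):
        t_end = signal.t[i1 - 1] + dt if i1 == len(signal) else signal.t[i1]
        intervals.append(ExerciseInterval(signal.t[i0], t_end, index=k))
    return intervals


def duration_metric(intervals: list[ExerciseInterval]) -> list[float]:
    """Duration (s) of each exercise: t_end - t_ini."""
    return [iv.duration for iv in intervals]


def rest_intervals(intervals: list[ExerciseInterval], t0: float,
                   t1: float) -> list[tuple[float, float]]:
    """Complement of the exercise intervals within [t0, t1)."""
    out = []
    cursor = t0
    for iv in intervals:
        if iv.t_ini > cursor:
            out.append((cursor, iv.t_ini))
        cursor = max(cursor, iv.t_end)
    if t1 > cursor:
        out.append((cursor, t1))
    return out
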
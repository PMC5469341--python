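"""Movement counting and epoching from angular-speed peaks.

Peaks of the angular-speed magnitude mark transitions between voluntary
hand movements (pick a piece up, transport it, place it, return). The
detector envelopes and smooths the signal, drops maxima too small to be
voluntary motion, and merges groups of near-coincident maxima into a
single movement. The Movements metric is the retained-peak count, and the
intervals between consecutive retained peaks are the movement epochs used
by the kinematic integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import PipelineConfig
from .io import ValidationError
from .segmentation import ExerciseInterval
from .signals import MagnitudeSeries, hanning_smooth, hilbert_envelope


@dataclass
class PeakSet:
    """Retained movement peaks inside one exercise."""

    times: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if len(self.times) != len(self.heights):
            raise ValidationError("times and heights must match in length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MovementSegment:
    """One movement epoch; consecutive segments tile the exercise."""

    t_start: float
    t_end: float
    index: int
    peak_t: tuple[float | None, float | None] = (None, None)
    flagged: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValidationError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _merge_close_peaks(times: np.ndarray, heights: np.ndarray,
                       gap_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Greedily merge peaks closer than gap_s, keeping the tallest of
    each group (a burst of nearby maxima is one movement)."""
    if len(times) == 0:
        return times, heights
    groups: list[list[int]] = [[0]]
    for i in range(1, len(times)):
        if times[i] - times[groups[-1][-1]] < gap_s:
            groups[-1].append(i)
        else:
            groups.append([i])
    keep = [grp[int(np.argmax(heights[grp]))] for grp in groups]
    return times[keep], heights[keep]


def detect_movement_peaks(somega: MagnitudeSeries,
                          interval: ExerciseInterval,
                          config: PipelineConfig | None = None) -> PeakSet:
    """Detect voluntary-movement peaks of S_omega inside an exercise.

    Pipeline: Hilbert envelope -> Hann smoothing (200 ms) -> local maxima;
    maxima below ``peak_min_height`` are skipped as artifacts, and maxima
    closer than ``peak_merge_gap_ms`` are treated as a single movement
    (the tallest is kept).
    """
    config = config or PipelineConfig()
    i0 = somega.index_of(interval.t_ini)
    i1 = somega.index_of(interval.t_end)
    if i1 - i0 < 3:
        raise ValidationError("interval must contain at least 3 samples")
    seg = MagnitudeSeries(somega.t[i0:i1], somega.values[i0:i1],
                          somega.kind, somega.fs)
    smooth = hanning_smooth(hilbert_envelope(seg), config.smooth_window_ms)
    # height skips absolutely small spikes; prominence rejects ripples
    # riding on sustained activity, which are not movement changes
    idx, props = find_peaks(smooth.values, height=config.peak_min_height,
                            prominence=config.peak_min_height)
    times, heights = _merge_close_peaks(
        smooth.t[idx], props["peak_heights"],
        config.peak_merge_gap_ms / 1000.0)
    return PeakSet(times, heights)


def movements_metric(peaks: PeakSet) -> int:
    """Movements = number of retained peaks (each marks a movement-change
    event)."""
    return len(peaks)


def epochs_from_peaks(peaks: PeakSet,
                      interval: ExerciseInterval) -> list[MovementSegment]:
    """Movement epochs between consecutive peaks, padded to the exercise.

    The first epoch starts at the exercise onset, the last ends at the
    exercise end, so the segments tile [t_ini, t_end) exactly. With fewer
    than 2 peaks a single flagged segment covering the whole interval is
    returned.
    """
    if len(peaks) < 2:
        return [MovementSegment(interval.t_ini, interval.t_end, 0,
                                (None, None), flagged=True)]
    bounds = [interval.t_ini, *peaks.times.tolist(), interval.t_end]
    segments = []
    for k in range(len(bounds) - 1):
        if bounds[k + 1] <= bounds[k]:  # peak exactly at a boundary
            continue
        left = bounds[k] if k > 0 else None
        right = bounds[k + 1] if k < len(bounds) - 2 else None
        segments.append(MovementSegment(bounds[k], bounds[k + 1],
                                        len(segments), (left, right)))
    return segments


def movement_economy(trainee_movements: int,
                     reference_movements: int) -> float:
    """Reference (expert) movement count over the trainee's count.

    Equals 1 when the trainee matches the reference and falls below 1
    when the trainee needs more movements.
    """
    if trainee_movements <= 0 or reference_movements <= 0:
        raise ValidationError("movement counts must be positive")
    return reference_movements / trainee_movements
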
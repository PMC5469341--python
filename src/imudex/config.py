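"""Pipeline configuration.

All tunables of the metric pipeline live in one dataclass so a run is fully
described by (recording, config). Durations are in the units their names
say; the sampling rate ``fs`` defaults to the glove's 100 Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

STANDARD_GRAVITY = 9.80665  # m/s^2

_DETREND_MODES = ("rest_baseline", "linear")


@dataclass
class PipelineConfig:
    """Parameters of the dexterity-metric pipeline.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz. All sensors are sampled at the same rate.
    g : float
        Gravitational acceleration magnitude subtracted from the
        accelerometer magnitude (m/s^2).
    exercise_threshold : float
        Comparator threshold on the angular-speed envelope (deg/s) that
        separates activity from rest; 15 deg/s is high enough to avoid
        false activations from involuntary movement.
    min_event_s : float
        Supra-threshold runs no longer than this are discarded as
        false positives (s).
    hole_fill_s : float
        Sub-threshold gaps no longer than this inside an activity period
        are filled (s).
    smooth_window_ms : float
        Length of the Hann smoothing window applied to the envelope
        before peak detection (ms).
    peak_min_height : float
        Minimum envelope height (deg/s) for a local maximum to count as a
        voluntary movement.
    peak_merge_gap_ms : float
        Maxima closer than this are merged into a single movement,
        keeping the tallest (ms).
    detrend_mode : str
        ``"rest_baseline"`` (subtract the rest-period mean, clamp at 0)
        or ``"linear"`` (subtract the least-squares line).
    rk_order : int
        Order of the Runge-Kutta velocity integrator; only 4 is
        implemented.
    va_zero_anchor : bool
        Apply a zero-velocity update at movement boundaries after
        integrating: each movement is assumed to start and end with the
        hand (near) still, so the linear trend that would make Va
        nonzero there is integration drift and is removed. Without it,
        accelerometer noise integrates into an unbounded random walk.
    """

    fs: float = 100.0
    g: float = STANDARD_GRAVITY
    exercise_threshold: float = 15.0
    min_event_s: float = 1.0
    hole_fill_s: float = 1.0
    smooth_window_ms: float = 200.0
    peak_min_height: float = 10.0
    peak_merge_gap_ms: float = 300.0
    detrend_mode: str = "rest_baseline"
    rk_order: int = 4
    va_zero_anchor: bool = True

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.exercise_threshold <= 0:
            raise ValueError("exercise_threshold must be positive")
        for name in ("min_event_s", "hole_fill_s", "smooth_window_ms",
                     "peak_merge_gap_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.detrend_mode not in _DETREND_MODES:
            raise ValueError(
                f"detrend_mode must be one of {_DETREND_MODES}, "
                f"got {self.detrend_mode!r}")
        if self.rk_order != 4:
            raise ValueError("only rk_order=4 is implemented")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return path

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
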
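"""Data model for glove recordings and CSV I/O.

A recording is a set of synchronously sampled 9-DOF sensor streams, one per
sensor on the glove (sensor 1 sits on the back of the hand, 2 on the thumb,
3 on the index finger, 4 on the middle finger). On disk a recording is a
long-format CSV with one row per (time, sensor) pair; see
:data:`RECORDING_COLUMNS` for the dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .config import PipelineConfig

RECORDING_COLUMNS = [
    "time_s", "sensor_id",
    "ax_mps2", "ay_mps2", "az_mps2",
    "gx_dps", "gy_dps", "gz_dps",
    "mx_uT", "my_uT", "mz_uT",
]

METRICS_COLUMNS = [
    "subject", "exercise", "sensor",
    "duration_s", "movements", "disp_m", "disptheta_deg",
]

SENSOR_POSITIONS = {1: "back of hand", 2: "thumb", 3: "index", 4: "middle"}


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


class ValidationError(ValueError):
    """In-memory data violates a structural invariant."""


class ImuSample(NamedTuple):
    """One 9-DOF sample; magnetometer components are None when absent."""

    t: float
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float
    mx: float | None = None
    my: float | None = None
    mz: float | None = None


@dataclass
class SensorStream:
    """Uniformly sampled tri-axial accel/gyro(/mag) series of one sensor.

    ``acc`` and ``gyr`` are (n, 3) arrays in m/s^2 and deg/s; ``mag`` is an
    optional (n, 3) array in microtesla. Timestamps are seconds from the
    start of the recording.
    """

    sensor_id: int
    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    mag: np.ndarray | None = None
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyr = np.atleast_2d(np.asarray(self.gyr, dtype=float))
        if self.mag is not None:
            self.mag = np.atleast_2d(np.asarray(self.mag, dtype=float))
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        if n < 2:
            raise ValidationError("stream needs at least 2 samples")
        for name, arr in (("acc", self.acc), ("gyr", self.gyr)):
            if arr.shape != (n, 3):
                raise ValidationError(f"{name} must have shape ({n}, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
        if self.mag is not None and self.mag.shape != (n, 3):
            raise ValidationError(f"mag must have shape ({n}, 3)")
        if not np.all(np.isfinite(self.t)) or self.t[0] < 0:
            raise ValidationError("timestamps must be finite and >= 0")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError(
                f"sensor {self.sensor_id}: timestamps must be strictly "
                "increasing")
        if np.max(np.abs(dt - 1.0 / self.fs)) > 0.1 / self.fs:
            raise ValidationError(
                f"sensor {self.sensor_id}: sampling interval deviates more "
                f"than 10% from 1/fs={1.0 / self.fs:.4g}s")

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[ImuSample]:
        has_mag = self.mag is not None
        for i in range(len(self.t)):
            yield ImuSample(
                self.t[i], *self.acc[i], *self.gyr[i],
                *(self.mag[i] if has_mag else (None, None, None)))

    @property
    def has_mag(self) -> bool:
        return self.mag is not None

    def slice(self, t0: float, t1: float) -> "SensorStream":
        """Half-open time slice [t0, t1)."""
        m = (self.t >= t0) & (self.t < t1)
        return SensorStream(
            self.sensor_id, self.t[m], self.acc[m], self.gyr[m],
            self.mag[m] if self.has_mag else None, self.fs)


@dataclass
class Recording:
    """All sensor streams of one subject's session plus free-form metadata."""

    subject_id: str
    streams: dict[int, SensorStream]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.streams:
            raise ValidationError("recording has no streams")
        fss = {s.fs for s in self.streams.values()}
        if len(fss) != 1:
            raise ValidationError("all streams must share fs")
        period = 1.0 / self.fs
        t0s = [s.t[0] for s in self.streams.values()]
        t1s = [s.t[-1] for s in self.streams.values()]
        if max(t0s) - min(t0s) > period or max(t1s) - min(t1s) > period:
            raise ValidationError(
                "streams must cover the same time span within one sample "
                "period")

    @property
    def fs(self) -> float:
        return next(iter(self.streams.values())).fs

    @property
    def sensor_ids(self) -> list[int]:
        return sorted(self.streams)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        if self.subject_id != other.subject_id:
            return False
        if self.sensor_ids != other.sensor_ids:
            return False
        for sid in self.sensor_ids:
            a, b = self.streams[sid], other.streams[sid]
            if a.has_mag != b.has_mag:
                return False
            if not (np.allclose(a.t, b.t) and np.allclose(a.acc, b.acc)
                    and np.allclose(a.gyr, b.gyr)):
                return False
            if a.has_mag and not np.allclose(a.mag, b.mag):
                return False
        return True


def read_recording(path: str | Path,
                   config: PipelineConfig | None = None) -> Recording:
    """Read a long-format recording CSV into a :class:`Recording`.

    Units are taken as declared in the header (m/s^2, deg/s, microtesla).
    Rows are sorted by time within each sensor; the magnetometer columns
    must be either fully present or fully empty per sensor.
    """
    config = config or PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if list(df.columns) != RECORDING_COLUMNS:
        raise FormatError(
            f"{path}: header must be exactly {','.join(RECORDING_COLUMNS)}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    streams: dict[int, SensorStream] = {}
    for sid, grp in df.groupby("sensor_id", sort=True):
        grp = grp.sort_values("time_s", kind="stable")
        t = grp["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"{path}: duplicate or non-monotone timestamps for sensor "
                f"{sid}")
        mag_vals = grp[["mx_uT", "my_uT", "mz_uT"]].to_numpy(float)
        n_nan = int(np.isnan(mag_vals).sum())
        if n_nan == 0:
            mag = mag_vals
        elif n_nan == mag_vals.size:
            mag = None
        else:
            raise ValidationError(
                f"{path}: sensor {sid} mixes present and absent "
                "magnetometer samples")
        streams[int(sid)] = SensorStream(
            int(sid), t,
            grp[["ax_mps2", "ay_mps2", "az_mps2"]].to_numpy(float),
            grp[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(float),
            mag, config.fs)
    return Recording(subject_id=path.stem, streams=streams)


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` in the standard long-format CSV dialect."""
    path = Path(path)
    frames = []
    for sid in rec.sensor_ids:
        s = rec.streams[sid]
        df = pd.DataFrame({
            "time_s": s.t,
            "sensor_id": sid,
            "ax_mps2": s.acc[:, 0], "ay_mps2": s.acc[:, 1],
            "az_mps2": s.acc[:, 2],
            "gx_dps": s.gyr[:, 0], "gy_dps": s.gyr[:, 1],
            "gz_dps": s.gyr[:, 2],
        })
        if s.has_mag:
            df["mx_uT"], df["my_uT"], df["mz_uT"] = (
                s.mag[:, 0], s.mag[:, 1], s.mag[:, 2])
        else:
            df["mx_uT"] = df["my_uT"] = df["mz_uT"] = np.nan
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)[RECORDING_COLUMNS]
    out.to_csv(path, index=False, float_format="%.9g")
    return path


def _window_mask(stream: SensorStream, window) -> np.ndarray:
    t0, t1 = (window.t_ini, window.t_end) if hasattr(window, "t_ini") \
        else (float(window[0]), float(window[1]))
    if t0 < stream.t[0] - 0.5 / stream.fs or t1 > stream.t[-1] + 1.0 / stream.fs:
        raise ValidationError("rest window lies outside the stream")
    mask = (stream.t >= t0) & (stream.t < t1)
    if mask.sum() < 0.5 * stream.fs:
        raise ValidationError("rest window must contain at least 0.5 s")
    return mask


def calibrate_offsets(stream: SensorStream, rest_window,
                      g: float | None = None,
                      rescale_accel: bool = True) -> SensorStream:
    """Remove static sensor offsets estimated over a rest window.

    Gyroscope channels get the rest-window mean subtracted per axis, which
    cancels constant rate bias (and hence linear angular-displacement
    drift). Accelerometer vectors are rescaled by one common factor so the
    rest-window mean of |a| equals g, making the rest-window mean of the
    gravity-compensated magnitude |a| - g zero. The operation is
    idempotent.

    ``rest_window`` is any (t_ini, t_end)-like pair or object inside the
    stream containing at least 0.5 s of samples. The accelerometer
    rescaling can be disabled: the scale factor is estimated from the
    rest window with a relative error of about sigma_a/(g*sqrt(n)), and
    on an unbiased accelerometer that estimation error — which the speed
    integrator turns into linear drift — is the larger effect.
    """
    from .config import STANDARD_GRAVITY
    g = STANDARD_GRAVITY if g is None else g
    mask = _window_mask(stream, rest_window)
    gyro_bias = stream.gyr[mask].mean(axis=0)
    scale = 1.0
    if rescale_accel:
        rest_norm = float(np.linalg.norm(stream.acc[mask], axis=1).mean())
        if rest_norm <= 0:
            raise ValidationError("rest-window accelerations are all zero")
        scale = g / rest_norm
    return SensorStream(
        stream.sensor_id, stream.t.copy(),
        stream.acc * scale, stream.gyr - gyro_bias,
        None if stream.mag is None else stream.mag.copy(), stream.fs)


def write_metrics(records, path: str | Path) -> Path:
    """Write per subject x exercise x sensor metric rows to CSV."""
    rows = [{
        "subject": r.subject, "exercise": r.exercise, "sensor": r.sensor,
        "duration_s": r.duration, "movements": r.movements,
        "disp_m": r.disp, "disptheta_deg": r.disp_theta,
    } for r in records]
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != METRICS_COLUMNS:
        raise FormatError(
            f"{path}: header must be exactly {','.join(METRICS_COLUMNS)}")
    return df
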
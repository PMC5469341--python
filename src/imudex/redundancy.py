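"""Inter-sensor redundancy and magnetometer-fusion analyses.

Two questions are addressed: (i) how much of the hand's kinematics is
shared across the glove's sensors — answered by Pearson correlation of
angular-speed magnitudes computed movement by movement and averaged — and
(ii) whether the magnetometers add information, answered by comparing the
gyro angular-speed magnitude S_omega with its counterpart SF_omega
reconstructed from finite differences of fusion-estimated absolute
orientation angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .config import PipelineConfig
from .io import SensorStream, ValidationError
from .movements import MovementSegment
from .signals import MagnitudeSeries


@dataclass
class CorrelationTable:
    """Segment-averaged Pearson correlation between two sensors."""

    pair: tuple[int, int]
    mean_r: float
    sd_r: float
    n_segments: int
    n_skipped: int = 0


@dataclass
class OrientationSeries:
    """Absolute orientation as intrinsic Z-Y-X Euler angles, degrees."""

    t: np.ndarray
    phi: np.ndarray    # roll, about x
    theta: np.ndarray  # pitch, about y
    psi: np.ndarray    # yaw, about z
    fs: float


def per_movement_correlation(somega_i: MagnitudeSeries,
                             somega_j: MagnitudeSeries,
                             segments: list[MovementSegment],
                             pair: tuple[int, int] = (0, 0)
                             ) -> CorrelationTable:
    """Pearson r between two angular-speed series, one value per movement
    segment, summarized by mean and sample standard deviation.

    Segments with fewer than 3 samples or zero variance in either series
    are skipped and counted in ``n_skipped``.
    """
    if len(somega_i) != len(somega_j) or not np.allclose(somega_i.t,
                                                         somega_j.t):
        raise ValidationError("series must share the same time grid")
    rs = []
    skipped = 0
    for seg in segments:
        i0 = somega_i.index_of(seg.t_start)
        i1 = somega_i.index_of(seg.t_end)
        a = somega_i.values[i0:i1]
        b = somega_j.values[i0:i1]
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            skipped += 1
            continue
        rs.append(pearsonr(a, b).statistic)
    if not rs:
        raise ValidationError("all segments degenerate")
    rs = np.asarray(rs)
    sd = float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0
    return CorrelationTable(pair, float(np.mean(rs)), sd, len(rs), skipped)


# ---------------------------------------------------------------------------
# Orientation fusion (gradient-descent quaternion complementary filter)

def _quat_to_euler_zyx(q: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    phi = np.degrees(np.arctan2(2 * (w * x + y * z),
                                1 - 2 * (x * x + y * y)))
    theta = np.degrees(np.arcsin(np.clip(2 * (w * y - z * x), -1.0, 1.0)))
    psi = np.degrees(np.arctan2(2 * (w * z + x * y),
                                1 - 2 * (y * y + z * z)))
    return phi, theta, psi


def _initial_quaternion(acc: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Tilt from the first accel sample, heading from the first mag
    sample (tilt-compensated)."""
    ax, ay, az = acc / np.linalg.norm(acc)
    roll = np.arctan2(ay, az)
    pitch = np.arctan2(-ax, np.hypot(ay, az))
    mx, my, mz = mag / np.linalg.norm(mag)
    # rotate mag into the horizontal plane
    mxh = mx * np.cos(pitch) + mz * np.sin(pitch)
    myh = (mx * np.sin(roll) * np.sin(pitch) + my * np.cos(roll)
           - mz * np.sin(roll) * np.cos(pitch))
    yaw = np.arctan2(-myh, mxh)
    cr, sr = np.cos(roll / 2), np.sin(roll / 2)
    cp, sp = np.cos(pitch / 2), np.sin(pitch / 2)
    cy, sy = np.cos(yaw / 2), np.sin(yaw / 2)
    return np.array([
        cy * cp * cr + sy * sp * sr,
        cy * cp * sr - sy * sp * cr,
        cy * sp * cr + sy * cp * sr,
        sy * cp * cr - cy * sp * sr,
    ])


def fuse_orientation(stream: SensorStream,
                     config: PipelineConfig | None = None,
                     beta: float = 0.1) -> OrientationSeries:
    """Absolute orientation angles from accel + gyro + mag fusion.

    A gradient-descent quaternion complementary filter: the quaternion is
    propagated with the gyro rates and corrected toward the direction
    that aligns the measured gravity and Earth-field vectors with their
    references, with correction gain ``beta`` (rad/s). ``beta = 0``
    degenerates to open-loop gyro integration. The filter is initialized
    from the first accel/mag sample.
    """
    if stream.mag is None:
        raise ValidationError("orientation fusion requires magnetometer "
                              "channels")
    gyr = np.radians(stream.gyr)
    acc, mag = stream.acc, stream.mag
    n = len(stream.t)
    q = _initial_quaternion(acc[0], mag[0])
    quats = np.empty((n, 4))
    quats[0] = q
    dts = np.diff(stream.t)
    for i in range(1, n):
        gx, gy, gz = gyr[i]
        w, x, y, z = q
        # quaternion rate from gyro: 0.5 * q (x) (0, omega)
        qdot = 0.5 * np.array([
            -x * gx - y * gy - z * gz,
            w * gx + y * gz - z * gy,
            w * gy - x * gz + z * gx,
            w * gz + x * gy - y * gx,
        ])
        a = acc[i]
        m = mag[i]
        na, nm = np.linalg.norm(a), np.linalg.norm(m)
        if na > 0 and nm > 0 and beta > 0:
            a = a / na
            m = m / nm
            # Earth-frame field reference (bx, 0, bz) from current estimate
            hx = (m[0] * (0.5 - y * y - z * z) + m[1] * (x * y - w * z)
                  + m[2] * (x * z + w * y)) * 2
            hy = (m[0] * (x * y + w * z) + m[1] * (0.5 - x * x - z * z)
                  + m[2] * (y * z - w * x)) * 2
            bx = np.hypot(hx, hy)
            bz = (m[0] * (x * z - w * y) + m[1] * (y * z + w * x)
                  + m[2] * (0.5 - x * x - y * y)) * 2
            # objective: predicted minus measured gravity / field
            f = np.array([
                2 * (x * z - w * y) - a[0],
                2 * (w * x + y * z) - a[1],
                2 * (0.5 - x * x - y * y) - a[2],
                bx * (0.5 - y * y - z * z) + bz * (x * z - w * y) - m[0],
                bx * (x * y - w * z) + bz * (w * x + y * z) - m[1],
                bx * (w * y + x * z) + bz * (0.5 - x * x - y * y) - m[2],
            ])
            J = np.array([
                [-2 * y, 2 * z, -2 * w, 2 * x],
                [2 * x, 2 * w, 2 * z, 2 * y],
                [0, -4 * x, -4 * y, 0],
                [-bz * y, bz * z, -2 * bx * y - bz * w,
                 -2 * bx * z + bz * x],
                [-bx * z + bz * x, bx * y + bz * w, bx * x + bz * z,
                 -bx * w + bz * y],
                [bx * y, bx * z - 2 * bz * x, bx * w - 2 * bz * y, bx * x],
            ])
            grad = J.T @ f
            norm = np.linalg.norm(grad)
            if norm > 0:
                qdot -= beta * grad / norm
        q = q + qdot * dts[i - 1]
        q = q / np.linalg.norm(q)
        quats[i] = q
    phi, theta, psi = _quat_to_euler_zyx(quats)
    return OrientationSeries(stream.t.copy(), phi, theta, psi, stream.fs)


def fusion_angular_speed(orient: OrientationSeries) -> MagnitudeSeries:
    """SF_omega: magnitude of the approximate Euler-angle rates.

    Angles are unwrapped (period 360 deg) before differentiation so a
    wrap across +-180 deg produces no derivative spike; derivatives are
    central differences with one-sided differences at the endpoints.
    """
    if len(orient.t) < 2:
        raise ValidationError("need at least 2 samples")
    rates = []
    for ang in (orient.phi, orient.theta, orient.psi):
        unwrapped = np.unwrap(ang, period=360.0)
        rates.append(np.gradient(unwrapped, orient.t))
    sf = np.sqrt(rates[0] ** 2 + rates[1] ** 2 + rates[2] ** 2)
    return MagnitudeSeries(orient.t, sf, "angular_speed_Somega", orient.fs)


def compare_fusion_vs_gyro(sf: MagnitudeSeries, somega: MagnitudeSeries,
                           max_lag_ms: float = 500.0
                           ) -> tuple[float, int]:
    """Best-lag Pearson r between SF_omega and S_omega.

    The fusion filter delays its output slightly, so r is maximized over
    integer-sample lags within +-max_lag_ms. Returns (best r, lag in
    samples); a positive lag means ``sf`` trails ``somega``.
    """
    if len(sf) != len(somega):
        raise ValidationError("series must share the same grid")
    a, b = sf.values, somega.values
    max_lag = int(round(max_lag_ms * sf.fs / 1000.0))
    best_r, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[lag:], b[:len(b) - lag]
        else:
            x, y = a[:len(a) + lag], b[-lag:]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            continue
        r = pearsonr(x, y).statistic
        if r > best_r:
            best_r, best_lag = r, lag
    return float(best_r), best_lag
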
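"""Parametric simulator of multi-sensor hand-motion IMU recordings.

The generator emulates the structure of a glove session: alternating rest
and exercise periods, and within each exercise a train of discrete
voluntary movements riding on a sustained low-amplitude activity
plateau. Each movement contributes a raised-cosine angular-speed pulse
about a movement-specific rotation axis that reverses at the speed peak
("reach, then return" — keeping the simulated hand orientation bounded
and making single-axis gyro traces oscillatory, as in real recordings)
and a biphasic acceleration pulse so the hand speed returns to ~0 at
each movement boundary. Gravity and the Earth's magnetic
field are rotated into the sensor frame with the orientation obtained by
integrating the planted angular velocity, so gravity compensation and
magnetometer fusion are exercised realistically. All sensors share the
hand's rigid motion and differ by independent per-axis Gaussian noise and
a static gyro bias.

Every planted quantity is recorded in a :class:`GroundTruth` with
closed-form totals (raised-cosine pulse area A*T/2; biphasic-sine path
A*L^2/(2*pi)), which is what the pipeline-recovery tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import STANDARD_GRAVITY
from .io import Recording, SensorStream, ValidationError

EARTH_FIELD_UT = np.array([22.0, 0.0, -42.0])  # north + down, sensor z up


@dataclass
class SyntheticProfile:
    """Generative parameters with planted ground truth.

    ``exercise_s`` and ``movements`` give the activity schedule (rest
    periods of ``rest_s`` seconds surround the exercises). Pulse
    amplitudes are drawn per movement from the given (mean, sd) and the
    pulse width is a fraction ~0.85 of the movement spacing, so
    movements blend into continuous activity the way real exercises do;
    ``baseline_dps`` is the sustained rotation between movement peaks.
    """

    exercise_s: tuple[float, ...] = (28.0, 14.0, 35.0)
    movements: tuple[int, ...] = (19, 10, 25)
    rest_s: float = 8.0
    pulse_peak_dps: tuple[float, float] = (110.0, 15.0)
    baseline_dps: float = 30.0
    ramp_s: float = 0.2
    width_frac: tuple[float, float] = (0.85, 0.03)
    accel_pulse_mps2: tuple[float, float] = (0.30, 0.05)
    finger_motion_dps: float = 15.0
    gyro_noise_sd_dps: float = 0.5
    accel_noise_sd_mps2: float = 0.01
    mag_noise_sd_ut: float = 0.3
    gyro_bias_dps: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fs: float = 100.0
    g: float = STANDARD_GRAVITY
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.exercise_s) != len(self.movements):
            raise ValidationError("one movement count per exercise needed")
        if any(d <= 0 for d in self.exercise_s) or self.rest_s <= 0:
            raise ValidationError("all durations must be positive")
        if any(m < 2 for m in self.movements):
            raise ValidationError("need at least 2 movements per exercise")
        for dur, m in zip(self.exercise_s, self.movements):
            if dur / m > 2.0:
                raise ValidationError(
                    "movements too sparse: spacing above 2 s breaks "
                    "activity continuity")


@dataclass
class GroundTruth:
    """Planted quantities of one simulated recording."""

    intervals: list[tuple[float, float]]
    movement_times: list[np.ndarray]
    movement_counts: list[int]
    disp_theta_deg: list[float]
    disp_m: list[float]
    meta: dict = field(default_factory=dict)

    @property
    def durations(self) -> list[float]:
        return [t1 - t0 for t0, t1 in self.intervals]


def _quat_mult(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _integrate_orientation(omega_rad: np.ndarray,
                           dt: float) -> np.ndarray:
    """Body->earth quaternions from body angular rates (axis-angle per
    step)."""
    n = len(omega_rad)
    quats = np.empty((n, 4))
    q = np.array([1.0, 0.0, 0.0, 0.0])
    quats[0] = q
    for i in range(1, n):
        w = omega_rad[i - 1]
        angle = np.linalg.norm(w) * dt
        if angle > 0:
            axis = w / np.linalg.norm(w)
            half = angle / 2.0
            dq = np.array([np.cos(half), *(np.sin(half) * axis)])
            q = _quat_mult(q, dq)
            q /= np.linalg.norm(q)
        quats[i] = q
    return quats


def _rotate_to_body(quats: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """R(q)^T @ vec for each quaternion (earth vector seen in the body
    frame)."""
    w, x, y, z = quats[:, 0], quats[:, 1], quats[:, 2], quats[:, 3]
    vx, vy, vz = vec
    # rows of R^T (= columns of R)
    out = np.empty((len(quats), 3))
    out[:, 0] = ((1 - 2 * (y * y + z * z)) * vx
                 + 2 * (x * y + w * z) * vy + 2 * (x * z - w * y) * vz)
    out[:, 1] = (2 * (x * y - w * z) * vx
                 + (1 - 2 * (x * x + z * z)) * vy
                 + 2 * (y * z + w * x) * vz)
    out[:, 2] = (2 * (x * z + w * y) * vx + 2 * (y * z - w * x) * vy
                 + (1 - 2 * (x * x + y * y)) * vz)
    return out


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    u = (t - center) / width
    pulse = np.where(np.abs(u) < 0.5, 0.5 * (1 + np.cos(2 * np.pi * u)),
                     0.0)
    return pulse


def _plateau(t: np.ndarray, t0: float, t1: float,
             ramp: float) -> np.ndarray:
    """Unit plateau on [t0, t1] with cosine ramps of length ``ramp``
    (closed-form area: (t1 - t0) - ramp)."""
    up = 0.5 * (1 - np.cos(np.pi * np.clip((t - t0) / ramp, 0, 1)))
    down = 0.5 * (1 - np.cos(np.pi * np.clip((t1 - t) / ramp, 0, 1)))
    return up * down


def generate_recording(profile: SyntheticProfile, n_sensors: int = 4,
                       subject_id: str | None = None
                       ) -> tuple[Recording, GroundTruth]:
    """Simulate one recording with planted ground truth.

    The same seed yields bit-identical output. Gyro channels carry the
    shared hand rotation plus per-sensor noise and bias; accelerometers
    carry the rotated gravity vector scaled so |a| - g equals the planted
    speed derivative; magnetometers carry the rotated Earth field.
    """
    rng = np.random.default_rng(profile.seed)
    fs, dt = profile.fs, 1.0 / profile.fs
    total = profile.rest_s + sum(d + profile.rest_s
                                 for d in profile.exercise_s)
    n = int(round(total * fs)) + 1
    t = np.arange(n) * dt

    s_omega = np.zeros(n)        # planted angular-speed magnitude (deg/s)
    axis_of = np.zeros((n, 3))   # rotation axis per sample
    axis_of[:, 2] = 1.0
    sa_true = np.zeros(n)        # planted speed derivative (m/s^2)
    activity = np.zeros(n)       # activity envelope, gates finger motion

    intervals, mv_times, mv_counts, dths, disps = [], [], [], [], []
    cursor = profile.rest_s
    peak_mu, peak_sd = profile.pulse_peak_dps
    frac_mu, frac_sd = profile.width_frac
    acc_mu, acc_sd = profile.accel_pulse_mps2

    for dur, m in zip(profile.exercise_s, profile.movements):
        t0, t1 = cursor, cursor + dur
        spacing = dur / m
        margin = 0.55 * spacing
        centers = np.linspace(t0 + margin, t1 - margin, m)
        centers = centers + rng.uniform(-0.04, 0.04, m) * spacing
        widths = np.clip(rng.normal(frac_mu, frac_sd, m), 0.78,
                         0.90) * spacing
        widths = np.maximum(widths, 0.3)
        amps = np.clip(rng.normal(peak_mu, peak_sd, m), 0.4 * peak_mu,
                       1.8 * peak_mu)

        # one rotation axis per movement, dominant z component; the
        # rotation reverses at each movement's speed peak ("reach, then
        # return"), so every movement cancels most of its net rotation:
        # orientation stays bounded and single-axis gyro traces
        # oscillate around zero like real ones, which is what lets
        # their Hilbert envelope localize activity
        axes = np.empty((m, 3))
        for j in range(m):
            xy = np.clip(rng.normal(0.0, 0.25, 2), -0.5, 0.5)
            u = np.array([xy[0], xy[1], 1.0])
            axes[j] = u / np.linalg.norm(u)

        # translation starts/ends a moment inside the activity window
        # (the hand leaves and returns to the table edge), which keeps
        # the planted speed zero across the onset/offset detection band
        bounds = np.concatenate(([t0 + 0.75 * margin], centers,
                                 [t1 - 0.75 * margin]))
        # sustained low-amplitude rotation over the whole exercise (the
        # hand is never still mid-exercise), ramped at the edges; it
        # keeps the activity envelope above the comparator threshold
        # between movement peaks. The plateau is inset by the envelope
        # spread of the edge detector (~0.16 s) so the planted interval
        # is what a threshold detector genuinely sees as activity.
        pad = 0.16
        plateau = _plateau(t, t0 + pad, t1 - pad, profile.ramp_s)
        s_omega += profile.baseline_dps * plateau
        activity += plateau
        # axis field: movement j owns [midpoint to previous peak,
        # midpoint to next peak) and flips sign at its own peak
        owns = np.concatenate(
            ([t0], 0.5 * (centers[:-1] + centers[1:]), [t1]))
        for j in range(m):
            pulse = amps[j] * _raised_cosine(t, centers[j], widths[j])
            s_omega += pulse
            lo = np.searchsorted(t, owns[j])
            mid = np.searchsorted(t, centers[j])
            hi = np.searchsorted(t, owns[j + 1])
            axis_of[lo:mid] = axes[j]
            axis_of[mid:hi] = -axes[j]
        acc_amps = np.clip(rng.normal(acc_mu, acc_sd, m + 1), 0.3 * acc_mu,
                           2.0 * acc_mu)
        for k in range(m + 1):
            b0, b1 = bounds[k], bounds[k + 1]
            span = b1 - b0
            lo, hi = np.searchsorted(t, b0), np.searchsorted(t, b1)
            sa_true[lo:hi] += acc_amps[k] * np.sin(
                2 * np.pi * (t[lo:hi] - b0) / span)

        intervals.append((t0, t1))
        mv_times.append(centers)
        mv_counts.append(m)
        # pulse areas A*w/2 plus the ramped plateau's baseline area
        base_area = profile.baseline_dps * (dur - 2 * pad
                                            - profile.ramp_s)
        dths.append(float(np.sum(amps * widths) / 2.0 + base_area))
        spans = np.diff(bounds)
        disps.append(float(np.sum(acc_amps * spans ** 2) / (2 * np.pi)))
        cursor = t1 + profile.rest_s

    omega_body = s_omega[:, None] * axis_of          # deg/s, body frame
    quats = _integrate_orientation(np.radians(omega_body), dt)
    grav_body = _rotate_to_body(quats, np.array([0.0, 0.0, 1.0]))
    acc_clean = grav_body * (profile.g + sa_true)[:, None]
    mag_clean = _rotate_to_body(quats, EARTH_FIELD_UT)

    # smooth independent finger motion for the finger sensors (2..4);
    # the back-of-hand sensor carries only the shared rigid motion
    smooth_win = np.hanning(int(round(0.5 * fs)))
    smooth_win /= np.sqrt(np.sum(smooth_win ** 2))

    streams = {}
    bias = np.asarray(profile.gyro_bias_dps, dtype=float)
    for sid in range(1, n_sensors + 1):
        gyr = (omega_body + bias
               + rng.normal(0.0, profile.gyro_noise_sd_dps, (n, 3)))
        if sid > 1 and profile.finger_motion_dps > 0:
            white = rng.normal(0.0, 1.0, (n, 3))
            finger = np.column_stack([
                np.convolve(white[:, k], smooth_win, mode="same")
                for k in range(3)])
            gyr += profile.finger_motion_dps * activity[:, None] * finger
        acc = acc_clean + rng.normal(0.0, profile.accel_noise_sd_mps2,
                                     (n, 3))
        mag = mag_clean + rng.normal(0.0, profile.mag_noise_sd_ut, (n, 3))
        streams[sid] = SensorStream(sid, t, acc, gyr, mag, fs)

    truth = GroundTruth(intervals, mv_times, mv_counts, dths, disps,
                        meta={"profile": profile.name,
                              "seed": profile.seed})
    rec = Recording(subject_id or f"{profile.name}-{profile.seed}",
                    streams, meta={"profile": profile.name,
                                   "seed": profile.seed})
    return rec, truth


_PRESETS = {
    # schedules chosen so the three tiers are strictly ordered in every
    # planted metric: duration, movement count, spatial and angular path
    "skilled": dict(exercise_s=(28.0, 14.0, 35.0), movements=(19, 10, 25),
                    pulse_peak_dps=(100.0, 12.0),
                    accel_pulse_mps2=(0.25, 0.04)),
    "average": dict(exercise_s=(30.0, 15.0, 55.0), movements=(20, 11, 38),
                    pulse_peak_dps=(110.0, 12.0),
                    accel_pulse_mps2=(0.30, 0.04)),
    "novice": dict(exercise_s=(32.0, 17.0, 78.0), movements=(21, 12, 51),
                   pulse_peak_dps=(120.0, 12.0),
                   accel_pulse_mps2=(0.35, 0.04)),
}


def preset(name: str, seed: int = 0, **overrides) -> SyntheticProfile:
    """A skill-tier profile: ``skilled``, ``average`` or ``novice``.

    The pegboard exercise (the third one) separates the tiers the most:
    a skilled profile completes it in 35 s with 25 movements, a novice
    needs 78 s and 51 movements. Keyword overrides replace any profile
    field.
    """
    if name not in _PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return SyntheticProfile(name=name, seed=seed, **params)


def truth_to_dict(truth: GroundTruth) -> dict:
    """JSON-serializable view of a ground truth."""
    return {
        "intervals": [list(iv) for iv in truth.intervals],
        "movement_times": [mt.tolist() for mt in truth.movement_times],
        "movement_counts": truth.movement_counts,
        "disp_theta_deg": truth.disp_theta_deg,
        "disp_m": truth.disp_m,
        "meta": truth.meta,
    }
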
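import numpy as np
import pytest

from imudex.io import SensorStream, ValidationError
from imudex.movements import MovementSegment
from imudex.redundancy import (compare_fusion_vs_gyro, fuse_orientation,
                               fusion_angular_speed,
                               per_movement_correlation)
from imudex.signals import angular_speed_magnitude
from imudex.simulate import EARTH_FIELD_UT, generate_recording, preset

from conftest import make_series


def segments_every(step, n_segs, t0=0.0):
    return [MovementSegment(t0 + k * step, t0 + (k + 1) * step, k)
            for k in range(n_segs)]


class TestPerMovementCorrelation:
    def test_identical_series(self):
        rng = np.random.default_rng(0)
        x = make_series(rng.normal(0, 10, 3000))
        ct = per_movement_correlation(x, x, segments_every(1.0, 30))
        assert ct.mean_r == pytest.approx(1.0)
        assert ct.sd_r == pytest.approx(0.0, abs=1e-12)

    def test_negated_series(self):
        rng = np.random.default_rng(1)
        x = make_series(rng.normal(0, 10, 3000))
        y = x.with_values(-x.values)
        ct = per_movement_correlation(x, y, segments_every(1.0, 30))
        assert ct.mean_r == pytest.approx(-1.0)

    def test_noise_attenuation_formula(self):
        """r = 1/sqrt(1 + 1/SNR) for signal + independent noise."""
        rng = np.random.default_rng(2)
        snr = (0.9 ** -2) - 1.0  # variance SNR giving r = 0.9
        snr = 1.0 / snr
        sig = rng.normal(0, 1.0, 30_000)
        noise = rng.normal(0, np.sqrt(1.0 / snr), 30_000)
        x = make_series(sig)
        y = make_series(sig + noise)
        ct = per_movement_correlation(x, y, segments_every(10.0, 30))
        assert ct.mean_r == pytest.approx(0.9, abs=0.05)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = make_series(rng.normal(0, 5, 2000))
        y = make_series(rng.normal(0, 5, 2000) + 0.8 * x.values)
        segs = segments_every(2.0, 10)
        a = per_movement_correlation(x, y, segs)
        y2 = y.with_values(3.0 * y.values + 7.0)
        b = per_movement_correlation(x, y2, segs)
        assert a.mean_r == pytest.approx(b.mean_r, abs=1e-12)

    def test_degenerate_segments_skipped_and_counted(self):
        x = make_series(np.concatenate([np.zeros(100),
                                        np.sin(np.arange(100))]))
        y = x.with_values(x.values.copy())
        ct = per_movement_correlation(x, y, segments_every(1.0, 2))
        assert ct.n_segments == 1 and ct.n_skipped == 1

    def test_all_degenerate_rejected(self):
        x = make_series(np.zeros(200))
        with pytest.raises(ValidationError):
            per_movement_correlation(x, x, segments_every(1.0, 2))

    def test_simulator_sensors_highly_correlated(self, config,
                                                 skilled_recording):
        from imudex.kinematics import segmentation_signal
        from imudex.movements import detect_movement_peaks, \
            epochs_from_peaks
        from imudex.segmentation import segment_exercises
        rec, _ = skilled_recording
        ivs = segment_exercises(segmentation_signal(rec.streams[1]),
                                config)
        soms = {sid: angular_speed_magnitude(s)
                for sid, s in rec.streams.items()}
        segs = epochs_from_peaks(
            detect_movement_peaks(soms[1], ivs[2], config), ivs[2])
        for i, j in [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]:
            ct = per_movement_correlation(soms[i], soms[j], segs, (i, j))
            assert ct.mean_r >= 0.8, (i, j, ct.mean_r)

    def test_finger_motion_lowers_correlation(self, config):
        from imudex.kinematics import segmentation_signal
        from imudex.movements import detect_movement_peaks, \
            epochs_from_peaks
        from imudex.segmentation import segment_exercises
        means = []
        for fm in (5.0, 30.0, 80.0):
            rec, _ = generate_recording(
                preset("skilled", seed=6, finger_motion_dps=fm))
            ivs = segment_exercises(segmentation_signal(rec.streams[1]),
                                    config)
            soms = {sid: angular_speed_magnitude(s)
                    for sid, s in rec.streams.items()}
            segs = epochs_from_peaks(
                detect_movement_peaks(soms[1], ivs[2], config), ivs[2])
            ct = per_movement_correlation(soms[2], soms[3], segs, (2, 3))
            means.append(ct.mean_r)
        assert means[0] > means[1] > means[2]


def stationary_stream(n=400, fs=100.0):
    t = np.arange(n) / fs
    acc = np.tile([0.0, 0.0, 9.80665], (n, 1))
    mag = np.tile(EARTH_FIELD_UT, (n, 1))
    return SensorStream(1, t, acc, np.zeros((n, 3)), mag, fs)


class TestFuseOrientation:
    def test_stationary_angles_constant(self):
        orient = fuse_orientation(stationary_stream(600))
        settled = slice(100, None)  # after 1 s
        for ang in (orient.phi, orient.theta, orient.psi):
            assert np.ptp(ang[settled]) < 0.5

    def test_vertical_rotation_rate_recovered(self):
        """Rotating about the vertical at 30 deg/s with consistent
        accel/mag, the fused yaw rate approximates the true rate."""
        fs, n = 100.0, 1500
        t = np.arange(n) / fs
        psi = np.radians(30.0 * t)
        acc = np.tile([0.0, 0.0, 9.80665], (n, 1))
        gyr = np.tile([0.0, 0.0, 30.0], (n, 1))
        c, s = np.cos(psi), np.sin(psi)
        bx, by, bz = EARTH_FIELD_UT
        mag = np.column_stack([c * bx + s * by, -s * bx + c * by,
                               np.full(n, bz)])
        stream = SensorStream(1, t, acc, gyr, mag, fs)
        orient = fuse_orientation(stream)
        rate = np.gradient(np.unwrap(orient.psi, period=360.0), t)
        settled = slice(200, None)
        assert np.mean(rate[settled]) == pytest.approx(30.0, rel=0.05)

    def test_open_loop_bias_drift(self):
        """With beta = 0 the filter is open-loop gyro integration, so a
        constant bias produces heading drift of about b*t."""
        s0 = stationary_stream(1000)
        b = 3.0  # deg/s about z
        stream = SensorStream(1, s0.t, s0.acc,
                              s0.gyr + [0.0, 0.0, b], s0.mag, s0.fs)
        orient = fuse_orientation(stream, beta=0.0)
        drift = np.unwrap(orient.psi, period=360.0)
        drift = drift - drift[0]
        t_end = s0.t[-1]
        assert abs(drift[-1]) == pytest.approx(b * t_end, rel=0.05)

    def test_missing_mag_rejected(self):
        s = stationary_stream(200)
        no_mag = SensorStream(1, s.t, s.acc, s.gyr, None, s.fs)
        with pytest.raises(ValidationError):
            fuse_orientation(no_mag)


class TestFusionAngularSpeed:
    def _orient(self, phi, theta, psi, fs=100.0):
        from imudex.redundancy import OrientationSeries
        n = len(phi)
        return OrientationSeries(np.arange(n) / fs, np.asarray(phi),
                                 np.asarray(theta), np.asarray(psi), fs)

    def test_constant_angles_give_zero(self):
        o = self._orient(np.full(100, 10.0), np.full(100, -5.0),
                         np.full(100, 170.0))
        assert np.allclose(fusion_angular_speed(o).values, 0.0)

    def test_linear_yaw_gives_constant_rate(self):
        t = np.arange(500) / 100.0
        o = self._orient(np.zeros(500), np.zeros(500), 30.0 * t)
        sf = fusion_angular_speed(o)
        assert np.allclose(sf.values, 30.0, rtol=1e-6)

    def test_wrap_produces_no_spike(self):
        t = np.arange(500) / 100.0
        psi = ((30.0 * t + 170.0 + 180.0) % 360.0) - 180.0  # wraps
        o = self._orient(np.zeros(500), np.zeros(500), psi)
        sf = fusion_angular_speed(o)
        assert np.max(sf.values) < 31.0


class TestCompareFusionVsGyro:
    def test_identical_series(self):
        rng = np.random.default_rng(5)
        x = make_series(np.abs(rng.normal(0, 10, 1000)))
        r, lag = compare_fusion_vs_gyro(x, x, 300.0)
        assert (r, lag) == (pytest.approx(1.0), 0)

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(6)
        base = np.convolve(rng.normal(0, 1, 1030), np.ones(10) / 10,
                           mode="same")
        x = make_series(base)
        y = make_series(np.roll(base, 3))  # y delayed by 3 samples
        r, lag = compare_fusion_vs_gyro(y, x, 100.0)
        assert lag == 3 and r > 0.99

    def test_symmetry_at_zero_lag(self):
        rng = np.random.default_rng(7)
        x = make_series(rng.normal(0, 1, 500))
        y = make_series(rng.normal(0, 1, 500) + 0.5 * x.values)
        r_xy, _ = compare_fusion_vs_gyro(x, y, 0.001)
        r_yx, _ = compare_fusion_vs_gyro(y, x, 0.001)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)

    def test_simulator_fusion_tracks_gyro(self, skilled_recording):
        rec, _ = skilled_recording
        s = rec.streams[1]
        sf = fusion_angular_speed(fuse_orientation(s))
        som = angular_speed_magnitude(s)
        r, _ = compare_fusion_vs_gyro(sf, som, 500.0)
        assert r > 0.82
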
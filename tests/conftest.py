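import numpy as np
import pytest

from imudex.config import PipelineConfig
from imudex.io import SensorStream
from imudex.signals import MagnitudeSeries
from imudex.simulate import generate_recording, preset

FS = 100.0


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


def make_series(values, fs=FS, kind="angular_speed_Somega"):
    values = np.asarray(values, dtype=float)
    return MagnitudeSeries(np.arange(len(values)) / fs, values, kind, fs)


def make_stream(n=200, acc=None, gyr=None, mag=None, fs=FS, sensor_id=1):
    t = np.arange(n) / fs
    if acc is None:
        acc = np.tile([0.0, 0.0, 9.80665], (n, 1))
    if gyr is None:
        gyr = np.zeros((n, 3))
    return SensorStream(sensor_id, t, acc, gyr, mag, fs)


def pulse_train(n, fs, centers, width, amp, noise_sd=0.0, rng=None):
    """Sum of raised-cosine pulses on a uniform grid."""
    t = np.arange(n) / fs
    x = np.zeros(n)
    for c in np.atleast_1d(centers):
        u = (t - c) / width
        x += np.where(np.abs(u) < 0.5,
                      amp * 0.5 * (1 + np.cos(2 * np.pi * u)), 0.0)
    if noise_sd:
        rng = rng or np.random.default_rng(0)
        x += rng.normal(0, noise_sd, n)
    return MagnitudeSeries(t, x, "angular_speed_Somega", fs)


@pytest.fixture(scope="session")
def skilled_recording():
    return generate_recording(preset("skilled", seed=1))


@pytest.fixture(scope="session")
def novice_recording():
    return generate_recording(preset("novice", seed=1))
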
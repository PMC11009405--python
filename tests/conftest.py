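import numpy as np
import pytest

from spiralbeta.kinematics import KinematicTrial
from spiralbeta.lfp import LfpEpoch
from spiralbeta.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Cohort config scaled down for fast tests."""
    return SimulationConfig(
        n_subjects=3,
        trials_per_condition=1,
        free_draw_duration=8.0,
        template_draw_duration=10.0,
        seed=42,
    )


def make_epoch(x, fs=200.0, t0=-6.0, draw_end=None, stim="off", intervals=None):
    """LfpEpoch wrapper with the standard rest/draw intervals."""
    x = np.asarray(x, float)
    if intervals is None:
        if draw_end is None:
            draw_end = t0 + x.size / fs
        intervals = {"rest": (-5.0, 0.0), "draw": (0.0, draw_end)}
    return LfpEpoch(signal=x, fs=fs, t0=t0, intervals=intervals, stim=stim)


def make_trial(t, x, y, **kw):
    return KinematicTrial(t=t, x=x, y=y, **kw)


@pytest.fixture
def sine_epoch():
    def _make(freq, amplitude=1.0, fs=2048.0, duration=12.0, stim="off"):
        t0 = -6.0
        t = t0 + np.arange(int(duration * fs)) / fs
        return make_epoch(amplitude * np.sin(2 * np.pi * freq * t), fs=fs, t0=t0,
                          stim=stim)

    return _make
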
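import numpy as np
import pytest

from zfswim.synth import SynthConfig, make_kinematics
from zfswim.synth.render import render_frames


@pytest.fixture(scope="session")
def config():
    return SynthConfig()


@pytest.fixture(scope="session")
def noiseless_config():
    return SynthConfig(sensor_noise_sd=0.0)


@pytest.fixture(scope="session")
def spontaneous_record(config):
    """A long spontaneous swimming record with ground truth (shared)."""
    return make_kinematics(config, duration_s=600.0, seed=11)


@pytest.fixture(scope="session")
def stationary_stack(noiseless_config):
    """Noise-free rendered frames of a stationary straight fish."""
    kin, _ = make_kinematics(noiseless_config, duration_s=0.01, seed=1, episodes=[])
    stack, midlines = render_frames(kin, None, noiseless_config, seed=0)
    bg = np.full(stack.frames.shape[1:], noiseless_config.background_level)
    return kin, stack, midlines, bg


@pytest.fixture(scope="session")
def bent_stack(noiseless_config):
    """Noise-free rendered frames of a C-bent fish (K = 90 deg)."""
    kin, _ = make_kinematics(noiseless_config, duration_s=0.004, seed=1, episodes=[])
    kin.K[:] = 90.0
    stack, midlines = render_frames(kin, None, noiseless_config, seed=0)
    bg = np.full(stack.frames.shape[1:], noiseless_config.background_level)
    return kin, stack, midlines, bg
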
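import numpy as np
import pytest

from festorque.muscle_sim import MuscleSimParams, simulate_session
from festorque.stim_protocol import ProtocolConfig, build_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_protocol():
    """Four identification cycles at 40 Hz (16 s, 640 loops)."""
    return build_sequence(ProtocolConfig(n_cycles=4, seed=0))


@pytest.fixture(scope="session")
def noiseless_session(short_protocol):
    params = MuscleSimParams(seed=0)
    return simulate_session(short_protocol, params)


@pytest.fixture(scope="session")
def noisy_session(short_protocol):
    params = MuscleSimParams(noise_sd_emg_mv=0.02, noise_sd_torque_nm=0.1, seed=0)
    return simulate_session(short_protocol, params)
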
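import numpy as np
import pytest

from dgquant.core import Trace
from dgquant.ephys_features import StepProtocol
from dgquant.synthetic_data import MembraneConfig, simulate_membrane


@pytest.fixture(scope="session")
def noiseless_membrane():
    """Noise-free LIF config shared by feature-recovery tests."""
    return MembraneConfig(noise_sd_mv=0.0)


@pytest.fixture(scope="session")
def step_protocol():
    return StepProtocol()


@pytest.fixture(scope="session")
def noiseless_sweeps(noiseless_membrane, step_protocol):
    """Full noise-free step family (computed once per session)."""
    return simulate_membrane(noiseless_membrane, step_protocol)


def make_trace(values, dt=0.05, units="mV"):
    return Trace(np.asarray(values, dtype=float), dt, units=units)
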
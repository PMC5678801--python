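import numpy as np
import pytest

from qbnoise import (build_interrupted, sample_photons, simulate_trajectory)


@pytest.fixture(scope="session")
def interrupted_model():
    """Moderate-flicker telegraph model: alpha=1/ms, k=0.05/ms (beta=20)."""
    return build_interrupted(alpha=1.0, k=0.05)


@pytest.fixture(scope="session")
def short_stream(interrupted_model):
    """A ~1 s trajectory + photon stream from the session model."""
    traj = simulate_trajectory(interrupted_model, 1000.0, seed=11)
    photons = sample_photons(interrupted_model, traj, seed=12)
    return traj, photons


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
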
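import numpy as np
import pytest

from hpwhmm.model import HPWParams, Trajectory
from hpwhmm.simulate import SimulationConfig, default_params, simulate


@pytest.fixture(scope="session")
def reference_params() -> HPWParams:
    """The reference simulation conditions (5 kHz, two-thirds confined)."""
    return default_params()


@pytest.fixture(scope="session")
def reference_sim(reference_params):
    """One 5000-frame trajectory at the reference conditions, with truth."""
    return simulate(SimulationConfig(params=reference_params, seed=11))


@pytest.fixture(scope="session")
def short_sim(reference_params):
    """A 1000-frame trajectory for cheaper sampler tests."""
    return simulate(
        SimulationConfig(params=reference_params, n_frames=1000, seed=7)
    )


@pytest.fixture()
def tiny_trajectory():
    """Hand-built 5-frame trajectory for scalar-by-scalar oracles."""
    times = np.array([0.0, 2e-4, 4e-4, 6e-4, 8e-4])
    positions = np.array(
        [
            [0.00, 0.00],
            [0.01, -0.005],
            [0.006, 0.004],
            [-0.002, 0.012],
            [0.005, 0.002],
        ]
    )
    return Trajectory(times=times, positions=positions, id="tiny")
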
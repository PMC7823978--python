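import numpy as np
import pytest

import leashwalk as lw


@pytest.fixture(scope="session")
def small_cohort():
    return lw.generate_cohort(15, seed=1)


@pytest.fixture(scope="session")
def small_design():
    return lw.build_design(15, 10, 3, seed=2)


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free simulation parameters: detection is then exact."""
    return lw.SimulationParams(noise_sd=0.0, accel_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_bundle(small_design, small_cohort):
    params = lw.SimulationParams(walk_duration=120.0)
    return lw.simulate_study(small_design, small_cohort, params, seed=7)


@pytest.fixture(scope="session")
def full_design():
    """The 74-walker x 5-walk crossed design over 111 dogs."""
    return lw.build_design(111, 74, 5, seed=11)


@pytest.fixture(scope="session")
def full_cohort():
    return lw.generate_cohort(111, seed=10)
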
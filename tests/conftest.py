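import numpy as np
import pytest

from adcscale.kinetics import (
    ActivationDistribution,
    FeedSchedule,
    KineticParameters,
    initial_state,
    molar_from_mass,
    simulate_0d,
)

MAB_MOLAR_MASS = 150000.0


@pytest.fixture(scope="session")
def default_params():
    return KineticParameters()


@pytest.fixture(scope="session")
def default_distribution():
    return ActivationDistribution()


@pytest.fixture(scope="session")
def standard_c_mab0():
    """Standard condition: 5 mg/mL antibody at 150 kDa."""
    return molar_from_mass(5.0, MAB_MOLAR_MASS)


@pytest.fixture(scope="session")
def standard_feed(standard_c_mab0):
    """5x molar payload excess fed at constant rate over 60 s."""
    return FeedSchedule("constant-rate", 60.0, 5.0 * standard_c_mab0, 10.0)


@pytest.fixture(scope="session")
def standard_trajectory(default_params, default_distribution, standard_c_mab0, standard_feed):
    init = initial_state(standard_c_mab0, default_distribution)
    return simulate_0d(init, default_params, standard_feed, 300.0, 0.1)
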
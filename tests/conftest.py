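import numpy as np
import pytest

from undx import forward, scenario


@pytest.fixture(scope="session")
def scenario_rates():
    return scenario.build_scenario()


@pytest.fixture(scope="session")
def scenario_waves(scenario_rates):
    """Noise-free survey waves at t = 99 and t = 101, integer ages."""
    ages = np.arange(55.0, 107.0)
    return (forward.cross_section_at(scenario_rates, 99.0, ages),
            forward.cross_section_at(scenario_rates, 101.0, ages))


@pytest.fixture(scope="session")
def inverse_ages():
    return np.arange(70.0, 101.0)


@pytest.fixture(scope="session")
def scenario_truth(scenario_rates, inverse_ages):
    t = np.full_like(inverse_ages, 100.0)
    return (scenario_rates.lambda0(t, inverse_ages),
            scenario_rates.lambda1(t, inverse_ages))


@pytest.fixture(scope="session")
def p_at_tprime(scenario_rates, inverse_ages):
    """Exact (p1, p2) of the forward solution at the reference time t'=100."""
    return forward.prevalence_at(scenario_rates, 100.0, inverse_ages)
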
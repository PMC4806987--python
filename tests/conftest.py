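import warnings

import numpy as np
import pytest

import haloresp as hr
from haloresp.model_core import ForwardOnlyWarning

warnings.simplefilter("ignore", ForwardOnlyWarning)


@pytest.fixture(scope="session")
def env():
    return hr.default_environment()


@pytest.fixture(scope="session")
def initial_state():
    return hr.default_initial_state()


@pytest.fixture(scope="session")
def en5():
    return hr.load_parameter_set("EN5")


@pytest.fixture(scope="session")
def eg1():
    return hr.load_parameter_set("EG1")


@pytest.fixture(scope="session")
def iondata():
    return hr.load_ion_dataset()


@pytest.fixture(scope="session")
def en5_trajectory(en5, env, initial_state):
    """EN5 integrated over the 5-hour horizon, shared across tests."""
    return hr.simulate(en5, env, initial_state, t_span=(0.0, 18000.0))


@pytest.fixture(scope="session")
def eg1_trajectory(eg1, env, initial_state):
    return hr.simulate(eg1, env, initial_state, t_span=(0.0, 18000.0))


def random_admissible_states(env, rng, n):
    """Uniformly sample states satisfying the model invariants (all
    intracellular pools positive, extracellular counterparts positive,
    ATP within the nucleotide pool)."""
    hi_cap = env.Htot * env.V_susp / env.a1
    ki_cap = env.Ktot * env.V_susp / env.a1
    nai_cap = env.Natot * env.V_susp / env.a1
    states = []
    for _ in range(n):
        states.append(hr.StateVector(
            Hi=10 ** rng.uniform(-9, np.log10(hi_cap * 0.9)),
            ATP=rng.uniform(1e-6, env.Atot * 0.999),
            Ki=10 ** rng.uniform(-2, np.log10(ki_cap * 0.9)),
            Nai=10 ** rng.uniform(-2, np.log10(nai_cap * 0.9)),
            dPsi=rng.uniform(-0.25, 0.25),
        ))
    return states
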
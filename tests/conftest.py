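import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_solver_logs(caplog):
    # solver non-convergence warnings are expected in loose-tolerance tests
    logging.getLogger("hdeeg.fgl_admm").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def scenario_problem(scenario: str, rng):
    """One scenario replicate packaged as (FglProblem, Theta0)."""
    from hdeeg import GroupedSamples
    from hdeeg.fgl_admm import empirical_covariances
    from hdeeg.simulate import gen_scenario

    X1, X2, Theta0 = gen_scenario(scenario, rng=rng)
    return empirical_covariances(GroupedSamples([X1, X2])), Theta0
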
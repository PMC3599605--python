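import numpy as np
import pytest

from obesim import ModelParams, State, headline_equilibrium, integrate


@pytest.fixture(scope="session")
def baseline_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def baseline_equilibrium(baseline_params):
    """The unique stable stationary state at the baseline parameter values."""
    head, all_points = headline_equilibrium(baseline_params)
    assert len(all_points) == 1
    return head


@pytest.fixture(scope="session")
def baseline_trajectory(baseline_params):
    """1000-year forward integration from the obesity-free start (N, 0, 0)."""
    return integrate(
        State(S=baseline_params.N, I=0.0, R=0.0), 1000.0, baseline_params
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20130309)
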
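import numpy as np
import pytest

from inspectgame import (
    InitialStateSpec,
    PayoffParams,
    SimulationConfig,
    Strategy,
    build_payoff_matrix,
)


@pytest.fixture
def fig5_params():
    """Payoff parameters of the minimal C+L+M interface experiment."""
    def make(beta):
        return PayoffParams(alpha=0.5, beta=beta, gamma=1.5)

    return make


@pytest.fixture
def zero_matrix():
    """All-zero payoff matrix (neutral imitation) for the minimal model."""
    return build_payoff_matrix(PayoffParams(0.0, 0.0, 0.0, fine=0.0), "minimal_CLM")


@pytest.fixture
def small_config():
    """A cheap three-strategy run for plumbing tests."""
    return SimulationConfig(
        variant="three_strategy",
        params=PayoffParams(alpha=0.5, beta=0.8, gamma=0.8),
        L=16,
        max_mcs=50,
        sample_every=5,
        seed=42,
    )


@pytest.fixture
def homogeneous_C_config():
    return SimulationConfig(
        variant="three_strategy",
        params=PayoffParams(alpha=0.5, beta=0.8, gamma=0.8),
        L=10,
        max_mcs=30,
        sample_every=5,
        seed=7,
        initial=InitialStateSpec("weighted_random", weights={Strategy.C: 1.0}),
    )
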
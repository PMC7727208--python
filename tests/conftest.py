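import numpy as np
import pytest

from priorcox.cox import MCMCSettings, ModelSpec
from priorcox.priors import build_vague_prior, pooled_inputs_from_answers
from priorcox.simulate import (
    ElicitationFixtureConfig,
    SimulationConfig,
    benefit_shift,
    generate_expert_answers,
    generate_trial,
)


@pytest.fixture(scope="session")
def panel_answers():
    """Answers from the default seven-expert panel for the renal factor."""
    return generate_expert_answers(ElicitationFixtureConfig(subgroup_factor="renal_risk"))


@pytest.fixture(scope="session")
def pooled_inputs(panel_answers):
    return pooled_inputs_from_answers(
        panel_answers, "renal_risk", benefit_shift("renal_risk")
    )


@pytest.fixture(scope="session")
def trial_500():
    """Seeded n=500 trial with moderate effects in both subgroups."""
    return generate_trial(SimulationConfig(n=500, theta1=0.2, theta2=0.3, seed=3))


@pytest.fixture(scope="session")
def vague_spec():
    return ModelSpec(prior=build_vague_prior())


@pytest.fixture
def fast_mcmc():
    return MCMCSettings(seed=11, chains=2, iterations=2000)


def random_pd_2x2(rng):
    """Random symmetric positive-definite 2x2 covariance."""
    A = rng.normal(size=(2, 2))
    return A @ A.T + 0.05 * np.eye(2)
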
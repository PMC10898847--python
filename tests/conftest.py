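import numpy as np
import pytest

from twostep.agent import ParameterSet, simulate_agent
from twostep.task import TaskConfig, generate_reward_walks


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def walks(default_config):
    return generate_reward_walks(default_config, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def make_agent_session(default_config, walks):
    """Factory: simulate one hybrid-agent session."""

    def _make(params=None, seed=0, config=None, w=None, **kwargs):
        params = params or ParameterSet(0.4, 1.0, 1.5, 0.5, 1.2)
        return simulate_agent(
            params, w or walks, config or default_config,
            np.random.default_rng(seed), **kwargs,
        )

    return _make
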
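import numpy as np
import pytest

from lakebandit import AgentParams, TaskConfig


@pytest.fixture
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture
def exploiter() -> AgentParams:
    """Agent that fully adopts the cue and exploits it for the rest of the block."""
    return AgentParams(
        alpha=0.5, beta=8.6,
        qboost_advice=1.0, qboost_observation=1.0,
        bboost_advice=50.0, bboost_observation=50.0,
    )


@pytest.fixture
def explorer() -> AgentParams:
    """Agent that adopts the cue's value but keeps exploring afterwards."""
    return AgentParams(
        alpha=0.5, beta=8.6,
        qboost_advice=1.0, qboost_observation=1.0,
        bboost_advice=0.4, bboost_observation=0.4,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
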
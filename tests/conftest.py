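import numpy as np
import pytest

from adhersim.agents import AgentParams
from adhersim.env import SessionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def config():
    return SessionConfig()


@pytest.fixture
def default_params():
    return AgentParams()


@pytest.fixture
def perfect_params():
    """Agent that always attempts, exactly on time, with the right code."""
    return AgentParams(p_attend=1.0, symptom_free_mult=1.0, timing_sd_s=0.0, p_wrong_code=0.0)


@pytest.fixture
def absent_params():
    """Agent that never attempts an entry."""
    return AgentParams(p_attend=0.0)
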
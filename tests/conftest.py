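import numpy as np
import pytest

from conseq.agent import AgentParams
from conseq.intention import IntentionParams
from conseq.learning import LearningParams
from conseq.neural import NeuralParams
from conseq.rescale import RescaleParams
from conseq.task import TaskConfig


@pytest.fixture
def cfg():
    return TaskConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def example_agent():
    """The example-simulation parameter set: G=0.3 (default horizon-1 gain),
    threshold 25 Hz, tau=80 ms, sigma=0.006/ms, phi0=0.5, k=0.4, sigma_psi=0.4."""
    return AgentParams(
        neural=NeuralParams(tau=80.0, sigma=0.006, delta_thr=0.025),
        intention=IntentionParams(sigma_psi=0.4),
        learning=LearningParams(k=0.4, phi0=0.5),
        rescale=RescaleParams(alpha=-0.018, beta=0.05),
    )


@pytest.fixture
def quiet_agent():
    """Nearly noiseless fast perceiver: reliable discrimination, no learning."""
    return AgentParams(
        neural=NeuralParams(tau=40.0, sigma=0.0005, delta_thr=0.02),
        intention=IntentionParams(sigma_psi=0.0),
        learning=LearningParams(k=0.0, phi0=(0.0, 1.0)),
        rescale=RescaleParams(alpha=-0.018, beta=0.08),
    )
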
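import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import affbound as ab

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_tensor(data, objects=None, actions=None, participants=None,
                groups=None):
    """Small ResponseTensor builder for hand-written arrays."""
    data = np.asarray(data, dtype=np.uint8)
    P, A, O = data.shape
    if objects is None:
        objects = [ab.ObjectItem(f"o{i}", 20.0 * (i + 1), 2 + i % 7)
                   for i in range(O)]
    if actions is None:
        actions = [ab.ActionItem(f"a{i}",
                                 "manipulation" if i % 2 == 0 else "whole_body")
                   for i in range(A)]
    if participants is None:
        participants = [f"p{i}" for i in range(P)]
    return ab.ResponseTensor(participants, actions, objects, data,
                             groups=groups)


@pytest.fixture(scope="session")
def human_config():
    """The human-scale recovery conditions: 24 objects over ranks 2-8,
    200 participants, agent 150 cm, logistic sharpness 4/octave, 5% lapse."""
    return ab.GeneratorConfig(n_participants=200, n_objects=24,
                              agent_size_cm=150.0, sharpness_beta=4.0,
                              lapse_rate=0.05, seed=0)


@pytest.fixture(scope="session")
def human_tensor(human_config):
    return ab.simulate(human_config)


@pytest.fixture(scope="session")
def human_aff(human_tensor):
    return ab.affordance_vectors(human_tensor)


@pytest.fixture(scope="session")
def human_report(human_tensor):
    return ab.run_analysis(
        human_tensor, ab.AnalysisConfig(n_permutations=1000, seed=0))
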
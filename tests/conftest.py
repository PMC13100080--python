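import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def neuron_params():
    from hhesn.neuron import default_neuron_params

    return default_neuron_params()


@pytest.fixture(scope="session")
def resting(neuron_params):
    from hhesn.neuron import resting_state

    return resting_state(neuron_params)


@pytest.fixture(scope="session")
def small_reference(neuron_params):
    """A short mixed-protocol reference run shared by reservoir/hybrid tests:
    200 ms training, 100 ms prediction continuation."""
    from hhesn.neuron import generate_reference
    from hhesn.stimulus import training_and_prediction_protocols

    train, pred = training_and_prediction_protocols(200.0, 100.0, seed=3)
    full = train.concat(pred)
    ref = generate_reference(neuron_params, full)
    return train, full, ref


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
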
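import numpy as np
import pytest

import pepqsar as pq


@pytest.fixture(scope="session")
def zscales():
    return pq.load_zscales()


@pytest.fixture(scope="session")
def as_printed():
    return pq.load_reference_dataset("as-printed")


@pytest.fixture(scope="session")
def canonical():
    return pq.load_reference_dataset("canonical")


@pytest.fixture(scope="session")
def reference_network():
    return pq.load_reference_network()


@pytest.fixture(scope="session")
def quick_config():
    """Cheap trainer settings for tests that only need a plausible model."""
    return pq.TrainingConfig(learning_rate=0.2, momentum=0.9,
                             max_epochs=1500, mse_goal=2.5e-3)


@pytest.fixture(scope="session")
def trained_model(as_printed, quick_config):
    """A small trained QsarModel on the benchmark (few restarts, cheap)."""
    result = pq.train_protocol(as_printed, hidden_size=7, config=quick_config,
                               restarts=3, seed=11)
    return pq.QsarModel(result.training.network, result.normalizer)


@pytest.fixture
def toy_net():
    """Tiny hand-checkable 2-input, 1-hidden network."""
    return pq.BPNetwork(iw=np.array([[0.3, -0.7]]), b1=np.array([0.1]),
                        lw=np.array([0.5]), b2=-0.2)
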
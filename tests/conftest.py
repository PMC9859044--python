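import numpy as np
import pytest

from cernanet.config import PipelineConfig
from cernanet.simulate import SimulationParams, simulate_dataset


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared simulated bundle for tests that only inspect it."""
    return simulate_dataset(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def labelled_sequences():
    """Shared coding/noncoding sequence pools for scorer tests."""
    from cernanet.simulate import random_coding_sequence, random_noncoding_sequence

    gen = np.random.default_rng(2024)
    coding = [random_coding_sequence(gen) for _ in range(200)]
    noncoding = [random_noncoding_sequence(gen) for _ in range(200)]
    return coding, noncoding
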
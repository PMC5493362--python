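import numpy as np
import pytest

from fuzzyair import GeneratorSpec, ModelConfig, build_default_system


@pytest.fixture(scope="session")
def default_system():
    return build_default_system()


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20071231)


@pytest.fixture()
def small_spec():
    """A short, fast synthetic series spec."""
    return GeneratorSpec(n_days=60, seed=7)
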
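import numpy as np
import pytest

from stemfate import ModelSpec


@pytest.fixture(scope="session")
def model1():
    return ModelSpec.from_preset("model1")


@pytest.fixture(scope="session")
def model2():
    return ModelSpec.from_preset("model2")


@pytest.fixture(scope="session")
def model3():
    return ModelSpec.from_preset("model3")


@pytest.fixture(scope="session")
def all_models(model1, model2, model3):
    return [model1, model2, model3]


@pytest.fixture(scope="session")
def custom_spec():
    """A non-preset but bounded coefficient set exercising every term."""
    return ModelSpec(alpha=0.3, beta=-0.8, gamma=0.9)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
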
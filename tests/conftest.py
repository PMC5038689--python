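import numpy as np
import pytest

from rcmldf import (
    BeamSpec,
    LensModel,
    TransportConfig,
    default_skin_model,
    model_for_preset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def healthy_model():
    return default_skin_model()


@pytest.fixture(scope="session")
def ksc1_model():
    return model_for_preset("ksc1")


@pytest.fixture(scope="session")
def ksc2_model():
    return model_for_preset("ksc2")


@pytest.fixture(scope="session")
def beam():
    return BeamSpec()


@pytest.fixture(scope="session")
def lens():
    return LensModel()


@pytest.fixture(scope="session")
def transport_config():
    return TransportConfig()
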
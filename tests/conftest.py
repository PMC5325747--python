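import numpy as np
import pytest

from tndecide.params import ModelConfig, Treatment, default_parameters


@pytest.fixture
def mvd_params():
    return default_parameters(Treatment.MVD)


@pytest.fixture
def srs_params():
    return default_parameters(Treatment.SRS)


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
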
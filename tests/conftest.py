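import numpy as np
import pytest

from cardionet.params import ModelParams, GatingRateParams
from cardionet.tissue import TimestepPolicy


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """Shipped calibrated defaults."""
    return ModelParams()


@pytest.fixture(scope="session")
def gating() -> GatingRateParams:
    return GatingRateParams()


@pytest.fixture
def policy() -> TimestepPolicy:
    return TimestepPolicy()


@pytest.fixture
def rng_np():
    return np.random.default_rng(2024)
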
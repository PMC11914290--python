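import numpy as np
import pytest

from emonorm import NormPolicy, Params


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def ebis():
    return NormPolicy.ebis(0.9)


@pytest.fixture
def image_scoring():
    return NormPolicy.image_scoring()


@pytest.fixture
def tiny_params():
    """Small, fast parameter set for unit-level dynamics tests."""
    return Params(z=12, generations=20, burn_in=5)
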
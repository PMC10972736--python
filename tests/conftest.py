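import numpy as np
import pytest

from inhibnet.models import IzhikevichParams, ViaParams
from inhibnet.synapses import PSCKernel


@pytest.fixture(scope="session")
def izh():
    return IzhikevichParams()


@pytest.fixture(scope="session")
def via():
    return ViaParams()


@pytest.fixture(scope="session")
def kernel():
    return PSCKernel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
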
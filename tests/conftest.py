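import pytest

from rnaworld._rng import BufferedRNG
from rnaworld.params import ParameterSet


@pytest.fixture
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture
def rng() -> BufferedRNG:
    return BufferedRNG(12345)
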
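import numpy as np
import pytest

from dabquant import ODChannel, StainVectors


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hdab():
    return StainVectors.hdab()


def make_channel(values, pixel_size=1.0):
    return ODChannel(np.asarray(values, dtype=float), pixel_size)


@pytest.fixture
def channel_factory():
    return make_channel
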
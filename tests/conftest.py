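import numpy as np
import pytest

from wobblefit.models import ExchangeModel, NucleusChannel


@pytest.fixture
def c13_channel():
    return NucleusChannel(id="T5-C4p", nucleus_kind="13C",
                          spectrometer_1h_freq=700.0, r1=2.0, r2=20.0)


@pytest.fixture
def n15_channel():
    return NucleusChannel(id="G15-N1", nucleus_kind="15N",
                          spectrometer_1h_freq=700.0, r1=1.5, r2=6.0)


@pytest.fixture
def two_state_model(c13_channel):
    return ExchangeModel(topology="two_state", p_b=0.002, kex_ab=1000.0,
                         dw_ab={c13_channel.id: 2.0})


@pytest.fixture
def star_model(c13_channel):
    return ExchangeModel(topology="star_three_state",
                         p_b=0.00075, kex_ab=4029.0,
                         p_c=0.08019, kex_ac=500.0,
                         dw_ab={c13_channel.id: 1.5},
                         dw_ac={c13_channel.id: 2.5})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
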
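import numpy as np
import pytest

from asbit.goldcode import GoldFamily, preferred_pair_specs, assign_identifier
from asbit.signal_model import ReceiverChain


@pytest.fixture(scope="session")
def family_m5():
    return GoldFamily(*preferred_pair_specs(5))


@pytest.fixture(scope="session")
def family_m7():
    return GoldFamily(*preferred_pair_specs(7))


@pytest.fixture(scope="session")
def ident511():
    """A 511-symbol truncated m=13 identifier (the hardware default)."""
    return assign_identifier(37, 511)


@pytest.fixture(scope="session")
def rx30():
    """Receiver chain at the reference 30 MSa/s grid, noise-free."""
    return ReceiverChain(sample_rate=30e6, noise_sigma=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
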
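import numpy as np
import pytest

from digestmap import EXAMPLE1, INS2_PRIME


@pytest.fixture
def example1():
    """Worked length-11 instance with 4 + 4 fragments."""
    return EXAMPLE1


@pytest.fixture
def ins2prime():
    """The adjusted (rounded-down) benchmark instance, total length 48."""
    return INS2_PRIME


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
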
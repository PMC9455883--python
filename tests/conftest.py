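import numpy as np
import pytest

from conngen import Population, derive_rng


@pytest.fixture
def rng():
    return derive_rng(12345)


@pytest.fixture
def pops():
    """A disjoint source/target pair (3 sources, 4 targets)."""
    return Population("S", 3), Population("T", 4, offset=3)


@pytest.fixture
def samepop():
    """A population projecting onto itself."""
    return Population("A", 4)
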
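import numpy as np
import pytest

from plantloc.tables import STANDARD_AA, default_group_table


@pytest.fixture(scope="session")
def table():
    return default_group_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_sequence(rng):
    """Factory for random valid sequences of a given or random length."""

    def make(length=None, lo=51, hi=500):
        if length is None:
            length = int(rng.integers(lo, hi + 1))
        return "".join(rng.choice(list(STANDARD_AA), size=length))

    return make
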
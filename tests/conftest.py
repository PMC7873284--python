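import numpy as np
import pytest

from srp3d.srp_core import make_rp_bank


@pytest.fixture(scope="session")
def bank():
    """Default n=2 projection bank shared by read-only tests."""
    return make_rp_bank(2, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_patch(rng):
    return rng.uniform(0.0, 255.0, size=(5, 5))


@pytest.fixture()
def random_volume(rng):
    return rng.uniform(0.0, 255.0, size=(10, 10, 5))
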
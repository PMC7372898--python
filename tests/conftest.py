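import numpy as np
import pytest

from hegwas.ckks import CkksContext
from hegwas.rns import generate_modulus_chain


@pytest.fixture(scope="session")
def small_chain():
    return generate_modulus_chain(30, 64, 5)


@pytest.fixture()
def small_ctx(small_chain):
    ctx = CkksContext(small_chain, seed=0)
    ctx.keygen(rotation_indices=(1, 2, 4, 8, -1, -4), relin_powers=(2, 3))
    return ctx


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
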
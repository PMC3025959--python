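import numpy as np
import pytest

from oligochip.fixtures import FixtureSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A compact fixture spec used by several module tests."""
    return FixtureSpec(seed=7, n_unigenes=10, n_spots=120, n_de_genes=12,
                       de_log2_fold=1.0)


def random_seq(rng, length, gc=0.43):
    at = 1.0 - gc
    return "".join(rng.choice(list("ATGC"), size=length,
                              p=[at / 2, at / 2, gc / 2, gc / 2]))
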
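import numpy as np
import pytest

from crisprlong.core import GuideSpec
from crisprlong.simulate import make_locus


@pytest.fixture(scope="session")
def locus600():
    """A 600-bp amplicon locus cut in the middle."""
    return make_locus(600, 0.5, 300, seed=11, name="amp")


@pytest.fixture(scope="session")
def guide():
    rng = np.random.default_rng(123)
    from crisprlong.core import random_dna
    return GuideSpec("g1", random_dna(rng, 20))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
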
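import numpy as np
import pytest
from hypothesis import settings

from minicircle.sequences import CircularSequence
from minicircle.sidd_model import EnergyParams

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Energy parameters sized for exhaustive small-circle checks."""
    return EnergyParams(r_max=2, n_max=8)


@pytest.fixture
def random_circle_factory(rng):
    def make(n_bp: int) -> CircularSequence:
        return CircularSequence("".join(rng.choice(list("ACGT"), n_bp)))

    return make
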
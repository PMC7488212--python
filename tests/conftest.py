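import numpy as np
import pytest

from confield.synth import build_flat_patch, build_subject, make_bar_stimulus


@pytest.fixture(scope="session")
def movie():
    """Default bar movie at a coarse-but-adequate grid resolution."""
    return make_bar_stimulus(grid_n=48)


@pytest.fixture(scope="session")
def small_patch():
    return build_flat_patch("V1", 5, 6, ecc_range=(0.5, 6.0))


@pytest.fixture(scope="session")
def pair_dataset():
    """V1 plus one extrastriate area, compact for fast fitting."""
    return build_subject({"V1": (7, 9), "V2d": (4, 7)})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
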
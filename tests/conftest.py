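import numpy as np
import pytest

from vtatlas.core import ImageFrame
from vtatlas.phantom import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-syllable, single-plane phantom cohort at 64 px for fast tests."""
    return generate_cohort(
        n_speakers=4, cv_list=("tu", "pa"), planes=("M",), image_size=64, seed=42
    )


@pytest.fixture(scope="session")
def phantom_frame(small_cohort):
    """One textured silence frame, useful as registration material."""
    return small_cohort.silence("SP1", "M")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_frame(rng):
    return ImageFrame(rng.uniform(0.0, 1.0, (32, 32)), plane="M")
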
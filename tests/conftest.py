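import numpy as np
import pytest

from nucleidict.core import Grid2D
from nucleidict.fixtures import FixtureConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sample():
    """A quick 96x96 fixture with a touching pair and two isolated nuclei."""
    cfg = FixtureConfig(
        grid=Grid2D(96, 96),
        n_nuclei=4,
        radius_range=(8.0, 8.0),
        touching_fraction=0.5,
        clutter_blobs=0,
        seed=3,
    )
    return generate(cfg)
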
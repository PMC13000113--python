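import numpy as np
import pytest

from cofi.encoding import make_mask_stack, make_schedule
from cofi.phantoms import SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A small scene grid that keeps rendering tests fast."""
    return SceneSpec(grid=(32, 40), pixel_pitch_um=15.0,
                     supersampling_factor=4, background_level=5.0)


@pytest.fixture
def tiny_masks():
    return make_mask_stack((6, 6), 4, 0.5, seed=3)


@pytest.fixture
def uniform20_schedule():
    return make_schedule("uniform", (20, 0.3, 0.15))
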
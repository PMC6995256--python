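import numpy as np
import pytest

from dynabody import build_schedule
from dynabody.synthetic import SyntheticClipSpec, make_clip


@pytest.fixture(scope="session")
def schedule():
    return build_schedule(seed=1)


@pytest.fixture(scope="session")
def small_clip_spec():
    """Desk-scale clip: same structure as the stimuli, smaller raster."""
    return SyntheticClipSpec(
        width=200, height=120, n_frames=20, moving_pixels_per_frame=60,
        noise_sd=2.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_clip(small_clip_spec):
    return make_clip(small_clip_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
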
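import numpy as np
import pytest

import stimrecon as sr


@pytest.fixture(scope="session")
def small_model():
    """100-neuron LNP population on an 18x18 frame, RFs tiling (3..15)^2."""
    return sr.make_reference_population(
        100, (3, 15, 3, 15), seed=0, frame_shape=(18, 18)
    )


@pytest.fixture(scope="session")
def gp_video_small():
    spec = sr.GPStimulusSpec(6.0, 6.0, height=18, width=18, duration=2.0)
    return sr.generate_gp_video(spec, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
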
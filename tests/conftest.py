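import numpy as np
import pytest

from kapurseg.fixtures import (
    SyntheticImageSpec,
    make_multimodal_image,
    reduce_gray_levels,
)
from kapurseg.segmentation import build_2d_histogram, nlm_filter


@pytest.fixture(scope="session")
def three_mode_image():
    """The standard 3-mode fixture: 128x128, means 30/128/220, sigma 8."""
    spec = SyntheticImageSpec(size=(128, 128), seed=0)
    return make_multimodal_image(spec)


@pytest.fixture(scope="session")
def hist16(three_mode_image):
    """L=16 joint histogram of the reduced standard fixture."""
    image, _ = three_mode_image
    small = reduce_gray_levels(image, 16)
    nlm = nlm_filter(small, window=21)
    return build_2d_histogram(small, nlm, L=16)
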
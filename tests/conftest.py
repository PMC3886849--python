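import numpy as np
import pytest

from gliaquant.synth_images import ImageSpec, IntensityImage, generate_section_image


@pytest.fixture
def small_spec():
    """A quick well-separated 96x96 section spec."""
    return ImageSpec(width=96, height=96, true_fraction=0.4, seed=11)


def make_image_from_values(values, bit_depth=8):
    """Column image with the given pixel values and a full-frame ROI."""
    pixels = np.asarray(values, dtype=np.uint8 if bit_depth == 8 else np.uint16)
    pixels = pixels.reshape(-1, 1)
    return IntensityImage(pixels=pixels, roi_mask=np.ones_like(pixels, dtype=bool),
                          bit_depth=bit_depth)


@pytest.fixture
def worked_bimodal_image():
    """The hand-computable bimodal section: symmetric background counts
    (1,3,5,3,1) at intensities 0..4 plus 10 signal pixels at 200."""
    values = [0] + [1] * 3 + [2] * 5 + [3] * 3 + [4] + [200] * 10
    return make_image_from_values(values)


@pytest.fixture
def background_only_image():
    """Symmetric background-only histogram (1,3,5,3,1); labeled area must be 0."""
    values = [0] + [1] * 3 + [2] * 5 + [3] * 3 + [4]
    return make_image_from_values(values)


@pytest.fixture
def well_separated_image(small_spec):
    return generate_section_image(small_spec)
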
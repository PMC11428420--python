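import numpy as np
import pytest

from ctdenoise.ct_io import CTImage, DomainTag
from ctdenoise.phantom import PhantomSpec, generate_clean_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    return PhantomSpec(image_size=64, seed=7)


@pytest.fixture
def clean_phantom(small_spec):
    img, shapes = generate_clean_phantom(small_spec, np.random.default_rng(7))
    return img, shapes


@pytest.fixture
def disk_image():
    """A centered disk of radius 20 on the background sentinel."""
    n, r = 64, 20.0
    yy, xx = np.mgrid[0:n, 0:n]
    mask = (yy - n / 2 + 0.5) ** 2 + (xx - n / 2 + 0.5) ** 2 <= r ** 2
    pixels = np.where(mask, 50.0, -2048.0)
    return CTImage(pixels=pixels, domain_tag=DomainTag.LOW_DOSE), r
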
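import numpy as np
import pytest

from fetalhc.geometry import Ellipse
from fetalhc.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ellipse(rng, image_size=96, a_range=(8.0, 30.0), ecc_range=(0.4, 1.0)):
    """A random valid ellipse whose enclosing box fits in the image."""
    a = rng.uniform(*a_range)
    b = a * rng.uniform(*ecc_range)
    theta = rng.uniform(0.0, 180.0)
    margin = a + 1
    cx = rng.uniform(margin, image_size - 1 - margin)
    cy = rng.uniform(margin, image_size - 1 - margin)
    return Ellipse(cx=cx, cy=cy, a=a, b=b, theta=theta)


@pytest.fixture
def clean_phantom():
    """A noise-free, gap-free phantom with flat background (easy oracle target)."""
    cfg = PhantomConfig(speckle=0.0, gap_fraction=0.0, background_texture=0.0)
    return generate_phantom(cfg, seed=7), cfg
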
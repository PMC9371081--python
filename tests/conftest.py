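import numpy as np
import pytest

from sfnet.synthetic import PhantomSpec, generate_phantom


@pytest.fixture
def rect_image():
    """A bright rectangle on a dark background with light seeded noise."""
    img = np.full((64, 64), 0.1)
    img[20:44, 16:48] = 0.9
    rng = np.random.default_rng(0)
    return np.clip(img + rng.normal(0, 0.01, img.shape), 0.0, 1.0)


@pytest.fixture
def phantom_pair():
    """Matched fractured/healthy phantoms sharing one geometry seed."""
    frac, _ = generate_phantom(PhantomSpec(side=96, fracture=True, seed=7, noise_sigma=0.02))
    healthy, _ = generate_phantom(PhantomSpec(side=96, fracture=False, seed=7, noise_sigma=0.02))
    return frac, healthy
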
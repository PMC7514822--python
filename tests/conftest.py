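import numpy as np
import pytest

from xraypipe.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, blur-free, upright phantom plus ground truth."""
    spec = PhantomSpec(noise_sigma=0.0, blur_sigma=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(noise_sigma=2.0, blur_sigma=0.7, rng_seed=42)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
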
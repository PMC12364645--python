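import numpy as np
import pytest

from qontour.phantoms import MarkerSpec, PhantomSpec, generate_phantom, make_marker


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Two-intensity 2D phantom: bright ellipse over dark background."""
    spec = PhantomSpec(shape=(48, 48), noise_sd=0.0, bias_amplitude=0.0, seed=0)
    img, truth = generate_phantom(spec)
    return img, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(shape=(48, 48), noise_sd=8.0, bias_amplitude=0.1, seed=3)
    img, truth = generate_phantom(spec)
    return img, truth


@pytest.fixture(scope="session")
def noisy_marker(noisy_phantom):
    _, truth = noisy_phantom
    return make_marker(truth, MarkerSpec(mode="noisy", error_rate=0.1, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
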
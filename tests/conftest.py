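import numpy as np
import pytest

from facestat import random_phase_pattern


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def texture_m2():
    """A 512x512 random-phase texture with power slope -2."""
    return random_phase_pattern(-2.0, size=512, seed=7)


@pytest.fixture(scope="session")
def texture_m275():
    """A 512x512 power-law texture near the slope of face photographs."""
    return random_phase_pattern(-2.75, size=512, seed=11)


def cosine_grating(n: int = 512, cycles: int = 8, amplitude: float = 50.0,
                   mean: float = 128.0, axis: int = 1) -> np.ndarray:
    """Grating varying along ``axis`` with an integer number of cycles."""
    x = np.arange(n)
    wave = amplitude * np.cos(2 * np.pi * cycles * x / n)
    img = np.full((n, n), mean)
    if axis == 1:
        return img + wave[None, :]
    return img + wave[:, None]
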
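import numpy as np
import pytest

from tmclass import make_grid


@pytest.fixture
def grid32():
    """Small grid: 3 µm field, 32 px, λ = 785 nm (1.2 NA fits Nyquist)."""
    return make_grid(3.0, 32, 0.785)


@pytest.fixture
def grid64():
    return make_grid(6.0, 64, 0.785)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
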
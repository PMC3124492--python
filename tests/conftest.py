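import numpy as np
import pytest

from stripquant import BackgroundRegion, SimSpec, simulate_cell_movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def corner_region():
    """Background region in the cell-free upper-left corner of a frame."""

    def make(shape, size=10):
        return BackgroundRegion.from_rectangle(shape, 0, 0, size, size)

    return make


@pytest.fixture
def clean_movie():
    """Zero-noise sigmoid-extension movie with its ground truth."""
    spec = SimSpec(noise_sd=0.0, seed=7)
    stack, truth = simulate_cell_movie(spec)
    return spec, stack, truth


@pytest.fixture
def noisy_movie():
    """Default-noise movie (SD 10 over background 20 / foreground ~200)."""
    spec = SimSpec(seed=7)
    stack, truth = simulate_cell_movie(spec)
    return spec, stack, truth
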
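import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_masked_roi(rng):
    """Small random grey-level grid with an irregular mask (holes allowed)."""
    def make(size=8, levels=6, mask_density=0.85, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        grid = r.integers(1, levels + 1, size=(size, size))
        mask = r.random((size, size)) < mask_density
        mask[0, 0] = True  # never fully empty
        return grid, mask
    return make
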
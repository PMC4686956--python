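import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250919)


@pytest.fixture
def image64(rng):
    """Seeded random 64x64 grayscale image in [0, 1]."""
    return rng.random((64, 64))


@pytest.fixture
def small_movie(image64):
    """Small SWIFT movie: 64x64, 3 levels, 8 harmonics, 40-frame cycles."""
    from swiftag import generate_movie

    return generate_movie(
        image64, levels=3, n_harmonics=8, frames_per_cycle=40, n_cycles=2, seed=7
    )
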
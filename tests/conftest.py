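import numpy as np
import pytest

from dermoborder import fixtures


@pytest.fixture(scope="session")
def disc_lesion():
    """Noise-free disc, radius 60 — the canonical convex shape."""
    return fixtures.make_regular_lesion(axes=(60.0, 60.0), noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_ellipse():
    """The standard noisy segmentation fixture (two-mode histogram)."""
    return fixtures.make_regular_lesion(
        size=256, axes=(60.0, 40.0), contrast=120.0, noise_sd=8.0, seed=1
    )


@pytest.fixture(scope="session")
def star_lesion():
    """Strongly perturbed blob: non-convex, fractal border."""
    return fixtures.make_irregular_lesion(
        roughness=0.35, harmonics=24, noise_sd=0.0, seed=2
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
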
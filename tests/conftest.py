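import numpy as np
import pytest

from ptmgan.fixtures import FixtureSpec, fixture_dataset


@pytest.fixture(scope="session")
def small_corpus():
    """Three well-separated classes, 40 samples each, with structure channels."""
    spec = FixtureSpec(
        {"A": 40, "B": 40, "C": 40}, motif_strength=0.8, struct_effect=1.2, seed=11
    )
    return fixture_dataset(spec)


@pytest.fixture(scope="session")
def gaussian_toy():
    """Two separated 4-D Gaussian classes for GAN behaviour tests."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-2, 0.5, (200, 4)), rng.normal(3, 0.5, (120, 4))])
    y = np.array([1] * 200 + [2] * 120)
    return X, y
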
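import numpy as np
import pytest

from specfood.spectral_scene import make_catalog, make_dataset


@pytest.fixture(scope="session")
def catalog():
    """4-class catalog with one confusable pair, planted at 850/970 nm."""
    return make_catalog(4, 1, 0.3, (10, 400), seed=1)


@pytest.fixture(scope="session")
def small_dataset(catalog):
    """20 noisy 64x64 scenes (5 per class) with 850 and 970 nm bands."""
    return make_dataset(catalog, 5, [850, 970], poses=2, noise_sd=0.02,
                        size=(64, 64), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
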
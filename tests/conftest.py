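import numpy as np
import pytest

from hybridac.phantoms import default_suite, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240616)


@pytest.fixture(scope="session")
def suite():
    return default_suite()


@pytest.fixture(scope="session")
def suite_images(suite):
    """name -> (image, truth, item) for every benchmark phantom."""
    out = {}
    for item in suite:
        img, truth = make_phantom(item.spec)
        out[item.name] = (img, truth, item)
    return out


@pytest.fixture
def two_phase_16x16():
    """Sharp 16x16 two-level image with a centered bright square."""
    img = np.full((16, 16), 0.2)
    img[4:12, 4:12] = 0.9
    truth = np.zeros((16, 16), bool)
    truth[4:12, 4:12] = True
    return img, truth
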
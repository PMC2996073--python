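import numpy as np
import pytest
from hypothesis import settings

import vierordt as v

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lok_atl_matrix():
    return v.preset_matrix("lok-atl")


@pytest.fixture(scope="session")
def atl_hctz_matrix():
    return v.preset_matrix("atl-hctz")


@pytest.fixture(scope="session")
def band_models():
    lok, atl, hctz = v.preset_band_models()
    return {"LOK": lok, "ATL": atl, "HCTZ": hctz}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def gaussian_spectrum(center=251.6, sigma=8.0, peak=0.8, grid=0.2,
                      lo=200.0, hi=400.0):
    """Single noiseless Gaussian band on a uniform grid."""
    wl = np.arange(lo, hi + grid / 2, grid)
    ab = peak * np.exp(-((wl - center) ** 2) / (2 * sigma**2))
    return v.Spectrum(wavelengths=wl, absorbances=ab)
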
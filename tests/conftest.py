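import numpy as np
import pytest

from marginscan import library as lib
from marginscan.spectral_processing import Spectrum, default_axis


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def coarse_axis():
    """Short axis (91 channels) for tests where spectral resolution is
    irrelevant but many model fits are needed."""
    return default_axis(step=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tissue_pair(axis):
    """Noiseless pure fatty / fibroadenomatoid spectra."""
    return (Spectrum(axis, lib.component("fatty").profile(axis)),
            Spectrum(axis, lib.component("fibroadenomatoid").profile(axis)))


@pytest.fixture(scope="session")
def phantom_library(axis):
    return [Spectrum(axis, lib.component(n).profile(axis),
                     {"component": n})
            for n in ("polymer_film", "soft_paper", "paraffin")]
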
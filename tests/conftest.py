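import numpy as np
import pytest

from simile import synthetic as syn
from simile.spectra_io import FragmentationSpectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pair():
    """A tiny 2+2 spectrum pair with easily enumerable structure."""
    x = FragmentationSpectrum("x", 200.0, np.array([100.0, 150.0]))
    y = FragmentationSpectrum("y", 220.0, np.array([120.0, 170.0]))
    return x, y


def random_pair(rng, max_size=6, mz_range=(50.0, 500.0)):
    m = int(rng.integers(1, max_size + 1))
    n = int(rng.integers(1, max_size + 1))
    x = syn.random_spectrum(m, mz_range, rng, spectrum_id="x")
    y = syn.random_spectrum(n, mz_range, rng, spectrum_id="y")
    return x, y
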
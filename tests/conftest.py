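import numpy as np
import pytest

from enetbeta.datamodel import SpectraDataset
from enetbeta.synthetic import generate_spectra


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng) -> SpectraDataset:
    """30 samples x 6 channels with a known 2-channel signal."""
    X = rng.standard_normal((30, 6))
    y = 2.0 * X[:, 1] - 1.5 * X[:, 4] + 0.1 * rng.standard_normal(30)
    return SpectraDataset(X, y)


@pytest.fixture
def spectrum_dataset():
    """Collinear spectrum-like dataset with planted sparse truth."""
    ds, truth = generate_spectra(n=200, p=40, k_true=3, rho=0.9, snr=100, seed=7)
    return ds, truth
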
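import numpy as np
import pytest

from npndiff import ObservedMatrix, band_precision, sample_nonparanormal


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_band_pair():
    """One seeded two-class draw from a band model with 5 flipped edges."""
    model = band_precision(20, 5, seed=11)
    obs1, lat1 = sample_nonparanormal(model, 80, 1, seed=21)
    obs2, lat2 = sample_nonparanormal(model, 80, 2, seed=22)
    return model, (obs1, lat1), (obs2, lat2)


@pytest.fixture
def gaussian_matrix():
    rng = np.random.default_rng(7)
    return ObservedMatrix(values=rng.normal(size=(60, 6)), class_label="a")
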
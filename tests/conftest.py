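import numpy as np
import pytest

from mconn import phantoms as ph
from mconn.image import ellipsoid_mask


@pytest.fixture(scope="session")
def functional_spec():
    """Study-condition phantom: 4 clusters x 3 components, w=0.6, one
    anticorrelated cluster pair, T=300, amplitude/sigma = 5."""
    return ph.default_functional_spec(n_timepoints=300, n_noise_components=0, seed=0)


@pytest.fixture(scope="session")
def noisy_spec():
    """Same phantom with two edge-shell noise components."""
    return ph.default_functional_spec(n_timepoints=300, n_noise_components=2, seed=0)


@pytest.fixture(scope="session")
def diffusion_spec():
    """Noiseless straight x-axis bundle phantom."""
    return ph.default_diffusion_spec()


@pytest.fixture(scope="session")
def brain_mask(functional_spec):
    return ellipsoid_mask(functional_spec.grid_shape)


@pytest.fixture(scope="session")
def simulated_subject(functional_spec):
    return ph.simulate_rsfmri(functional_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
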
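import numpy as np
import pytest

from retinotune import load_reference_pigments
from retinotune.synthetic import SyntheticSpec, synth_median_table


@pytest.fixture(scope="session")
def reference_pigments():
    """The bundled 11-pigment table of measured λ_max values."""
    return load_reference_pigments()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Synthetic modelling table generated exactly from the published model."""
    spec = SyntheticSpec(seed=11, noise_sigma_nm=0.0)
    dataset, truth = synth_median_table(spec)
    return dataset, truth, spec


@pytest.fixture(scope="session")
def noisy_dataset():
    """Synthetic modelling table at the default (study-scale) noise level."""
    spec = SyntheticSpec(seed=11)
    dataset, truth = synth_median_table(spec)
    return dataset, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
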
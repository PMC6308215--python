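import numpy as np
import pytest

from ppbqsar.descriptor_model import compute_descriptors, prefilter
from ppbqsar.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic compounds shared by descriptor/AD tests."""
    return generate_dataset(SyntheticConfig(n_compounds=60, seed=3))


@pytest.fixture(scope="session")
def small_descriptors(small_dataset):
    return prefilter(compute_descriptors(small_dataset))


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 500 compounds, generator seed 0."""
    return generate_dataset(SyntheticConfig(n_compounds=500, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
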
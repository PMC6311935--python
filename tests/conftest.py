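import numpy as np
import pytest
from hypothesis import settings

import mampep as mp

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_allele():
    """The default planted-motif allele: 9-mers, anchors at sites 2 and 9."""
    return mp.make_allele(seed=0)


@pytest.fixture(scope="session")
def small_data(default_allele):
    """A small balanced dataset sampled from the default allele."""
    return mp.sample_peptides(default_allele, 120, 120, seed=1)


@pytest.fixture(scope="session")
def small_split(small_data):
    return mp.split_dataset(small_data, 0.2, seed=1)


@pytest.fixture(scope="session")
def tiny_config():
    """A short training schedule for unit tests (not the study conditions)."""
    return mp.TrainConfig(max_epochs=40, patience=10, batch_size=32,
                          n_models=2, seed=0)


@pytest.fixture(scope="session")
def tiny_ensemble(small_split, tiny_config):
    train, _ = small_split
    return mp.train_ensemble(train, tiny_config)


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(mp.AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))
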
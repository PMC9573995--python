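import numpy as np
import pytest

import kinclass as kc


@pytest.fixture(scope="session")
def small_dataset() -> kc.PairDataset:
    """60 families x 4,000 LE loci, error-free; shared across unit tests."""
    return kc.build_pair_dataset(60, 0.0, 4000, seed=11)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return kc.extract_features(small_dataset)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
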
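import warnings

import numpy as np
import pytest

from circlearn.pipeline import featurize
from circlearn.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted dataset shared across tests (30 + 30 records)."""
    return generate(SyntheticConfig(n_pos=30, n_neg=30,
                                    length_range=(300, 400), seed=11))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    ds = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X = featurize(ds.records, tracks=ds.tracks, k=3, flank_L=100,
                      graph_n_bits=12, seed=11)
    return X, ds.labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
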
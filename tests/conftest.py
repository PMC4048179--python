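import numpy as np
import pytest

from structmap.datatypes import TraitMatrix
from structmap.preprocess import standardize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_regression(rng, n=25, J=8, K=3, n_causal=2):
    """Standardized (X, Y) with a planted linear signal."""
    X, _ = standardize(rng.normal(size=(n, J)))
    signal = X[:, :n_causal] @ rng.normal(size=(n_causal, K))
    Y, _ = standardize(signal + rng.normal(size=(n, K)))
    return X, Y


@pytest.fixture
def small_xy(rng):
    return random_regression(rng)


def trait_matrix(values, kind="expression", prefix="trait"):
    n, K = values.shape
    return TraitMatrix(
        values,
        trait_ids=[f"{prefix}{k}" for k in range(K)],
        sample_ids=[f"s{i}" for i in range(n)],
        kind=kind,
    )
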
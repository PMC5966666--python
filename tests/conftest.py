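import numpy as np
import pytest

from cardiodbn.datasets import SyntheticConfig, generate_synthetic
from cardiodbn.preprocessing import Preprocessor
from cardiodbn.rbm import RBMParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params(rng):
    """A random 3-visible x 2-hidden RBM with modest weights."""
    return RBMParams(
        w=rng.normal(0, 0.5, size=(3, 2)),
        a=rng.normal(0, 0.5, size=3),
        b=rng.normal(0, 0.5, size=2),
    )


@pytest.fixture(scope="session")
def synthetic_records():
    """Mid-size hierarchical fixture shared across integration tests."""
    return generate_synthetic(
        SyntheticConfig(n_samples=300, latent_depth=2, seed=42)
    )


@pytest.fixture(scope="session")
def encoded_synthetic(synthetic_records):
    X, y = Preprocessor().fit_transform(synthetic_records)
    return X, y
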
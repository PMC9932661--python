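import numpy as np
import pytest

from drpred import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """200 samples, mixed kinds, 4 informative features, gamma shape 5."""
    return simulate_dataset(
        200, n_rna=60, n_cnv=20, n_mut=10, n_informative=4, shape_k=5.0, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
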
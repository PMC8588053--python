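import numpy as np
import pytest

from afmpore import PairConfig, fixture_gamma_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tapping_pair():
    """100 vs 1000 kDa tapping-mode bootstrap configuration (n = 60 per class)."""
    return PairConfig(
        gamma_a=fixture_gamma_params("tapping", 100),
        gamma_b=fixture_gamma_params("tapping", 1000),
        n_a=60,
        n_b=60,
        n_datasets=10,
        eval_fraction=0.8,
        seed=7,
    )
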
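import numpy as np
import pytest

from sporesense import BindingParams


@pytest.fixture(scope="session")
def fitted_params() -> BindingParams:
    """Published dissociation constants with unit maximal rate."""
    return BindingParams(alpha=1.0, k_l=0.026, k_d=0.0052)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
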
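import numpy as np
import pytest

from ncreann.synthetic import CoupledSystemSpec


@pytest.fixture
def var1_spec():
    """Small stationary 2-channel VAR(1) with one cross coupling."""
    coeffs = np.zeros((2, 2, 1))
    coeffs[0, 0, 0] = 0.5
    coeffs[1, 1, 0] = 0.3
    coeffs[1, 0, 0] = 0.4  # 0 -> 1
    return CoupledSystemSpec(n_channels=2, order=1, linear_coeffs=coeffs,
                             noise_sd=1.0, samples_per_trial=800, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
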
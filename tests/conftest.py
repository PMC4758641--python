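import numpy as np
import pytest

from attnnet import ModelParameters, calibrate


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Default global parameter set with calibrated normalization constants."""
    return calibrate(ModelParameters())


@pytest.fixture(scope="session")
def small_params() -> ModelParameters:
    """Tiny configuration for brute-force oracle comparisons.

    Kernel scales are shrunk so that the truncated kernels fit a 9x9
    canvas; the oracle implements the same truncated-kernel definitions
    by direct summation.
    """
    return ModelParameters(sigma_bottom=1.0, sigma_top=2.0, sigma_inh=1.0,
                           wavelength=2.0, canvas=(9, 9),
                           c_bottom=0.5, c_top=0.01)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
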
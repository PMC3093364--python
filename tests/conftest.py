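import numpy as np
import pytest

from centrodyn.synthetic_imaging import ImagingParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_free_params():
    return ImagingParams(poisson_noise=False, read_sigma=0.0)


@pytest.fixture
def default_params():
    return ImagingParams()
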
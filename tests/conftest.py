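import numpy as np
import pytest

from microaqua.thermo import default_model


@pytest.fixture(scope="session")
def model():
    """Default Margules model calibrated to the 0.7 wt% dissolved-water anchor."""
    return default_model()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
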
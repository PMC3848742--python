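import numpy as np
import pytest

from myoffr.config import fast_test_config, full_config


@pytest.fixture(scope="session")
def cfg():
    """Coarse desk-scale configuration used throughout the suite."""
    return fast_test_config()


@pytest.fixture(scope="session")
def cfg_full():
    return full_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
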
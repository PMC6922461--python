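import warnings

import numpy as np
import pytest


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Silence identifiability warnings that deliberately-degenerate test
    inputs trigger; tests that assert on warnings re-enable them."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
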
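import numpy as np
import pytest

from clutchsim import default_params, make_preset


@pytest.fixture
def base_params():
    """Fresh default (WT) parameter set."""
    return default_params()


@pytest.fixture
def fast_rigid():
    """Small, quick rigid-engine configuration for unit tests."""
    p = make_preset("BBS", model="rigid")
    p.duration = 5.0
    p.seed = 42
    return p


@pytest.fixture
def fast_visco():
    """Small, quick viscoelastic configuration for unit tests."""
    p = make_preset("BBS", model="visco")
    p.duration = 5.0
    p.seed = 42
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
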
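import numpy as np
import pytest

from smtether.binding import BindingParams
from smtether.polymer import WLCParams


@pytest.fixture
def wlc_params() -> WLCParams:
    """Bare B-DNA mechanics: P = 50 nm, B = 0.34 nm/bp, S = 1200 pN."""
    return WLCParams(P_ds=50.0, B_ds=0.34, S_ds=1200.0, kT=4.11)


@pytest.fixture
def binding_params() -> BindingParams:
    """Combined binding estimates: K_D = 2.3 nM, omega = 23, n = 26 bp."""
    return BindingParams(K_D=2.3, omega=23.0, n=26)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
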
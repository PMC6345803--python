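import numpy as np
import pytest

from septcurve import SeptinModelParams


@pytest.fixture
def params() -> SeptinModelParams:
    """Default single-filament parameters (a1 = 4 nm, Lp1 = 2 µm,
    dg1_flat = -0.7305 kT/nm)."""
    return SeptinModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
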
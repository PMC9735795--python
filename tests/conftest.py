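import numpy as np
import pytest

from zfthermo.speciation import Chelator


@pytest.fixture
def edta_like() -> Chelator:
    """EDTA-like chelator: four protonation steps, strong 1:1 Zn complex."""
    return Chelator("EDTA-like", [10.19, 6.13, 2.69, 2.00], 16.5)


@pytest.fixture
def wide_ph_grid() -> np.ndarray:
    """pH grid sampling through both thiol transitions (needed to identify
    a pK2 near 8.8; the instrument window itself stops near pH 8)."""
    return np.round(np.arange(3.0, 10.0 + 1e-9, 0.1), 10)
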
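import numpy as np
import pytest

from copulse.io import Trace
from copulse.synth import SynthConfig, triangular_kernel


@pytest.fixture
def grid_2min():
    """7-h observation at 2-min frames."""
    return np.arange(0, 422, 2.0)


@pytest.fixture
def triangle_trace():
    """One noiseless triangular pulse: amplitude 10, FWHM 10 min, apex t=20."""
    t = np.arange(0, 62, 2.0)
    v = triangular_kernel(t, 20.0, 10.0, 10.0)
    return Trace("c0", "MSN2", t, v)


@pytest.fixture
def small_cfg():
    return SynthConfig(n_cells=20, duration_min=420.0, seed=42)
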
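import numpy as np
import pytest

from efeiod import LatticeParams


@pytest.fixture
def example3_params():
    """3-site chain, footprint 2, uniform unit rates, 1% drop-off, no forces."""
    return LatticeParams.homogeneous(3, 2, lam=1.0, alpha=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
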
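import numpy as np
import pytest

from histomech import ViscoParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def visco_truth():
    """Reference material parameters at the soft-tissue stiffness scale."""
    return ViscoParams(c_a=1500.0, c_b=2.0, c_m=500.0, eta1=400.0, eta2=4000.0)
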
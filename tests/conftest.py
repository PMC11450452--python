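import numpy as np
import pytest

from colspike.synapse import SynapseParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spspk_params():
    """Sparse-spiking trace parameters (f_max = 100 Hz, dt = 1 ms)."""
    return SynapseParams(tau_zi=0.020, tau_zj=0.020, tau_p=5.0,
                         f_max=100.0, dt=0.001)
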
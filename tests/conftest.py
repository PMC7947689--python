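import numpy as np
import pytest

from ucnsim import (
    UCNParams,
    default_jeffress_network,
    run_itd_sweep,
)


@pytest.fixture(scope="session")
def default_params() -> UCNParams:
    return UCNParams()


@pytest.fixture(scope="session")
def jeffress_net():
    """Study network: per-segment delay calibrated to 20 μs, 3 outputs."""
    return default_jeffress_network(20.0)


@pytest.fixture(scope="session")
def nominal_sweep(jeffress_net):
    """±60 μs, 1 μs step sweep of the matched network (shared, it is the
    most expensive fixture)."""
    return run_itd_sweep(jeffress_net, np.arange(-60.0, 60.5, 1.0))
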
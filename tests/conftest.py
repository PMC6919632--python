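import numpy as np
import pytest

import esskit as ek


@pytest.fixture(scope="session")
def xyz_snapshot():
    """300 cells of X+Y<->Z (k1=k-1=1) at t=100, lognormal(4,4) initials."""
    net = ek.toy_network("xyz")
    init = ek.sample_initial_conditions(net, 300, seed=101)
    return ek.integrate_ensemble(net, init, [100.0]).final()


@pytest.fixture(scope="session")
def cycle3_result():
    """300 cells of the cycle A->B<->C->A (all rates 1) at t=100."""
    net = ek.toy_network("cycle3")
    init = ek.sample_initial_conditions(net, 300, seed=102)
    return net, ek.integrate_ensemble(net, init, [100.0])


@pytest.fixture(scope="session")
def kp_snapshot():
    """300 cells of the kinase/phosphatase system at t=100."""
    net = ek.toy_network("kinase_phosphatase")
    init = ek.sample_initial_conditions(net, 300, seed=103)
    return ek.integrate_ensemble(net, init, [100.0]).final()


@pytest.fixture(scope="session")
def two_cluster_snapshot():
    """Lognormal two-cluster mixture, 90/10 weights, well separated."""
    rng = np.random.default_rng(104)
    logs = np.vstack(
        [rng.normal([0.0, 0.0], 1.0, (900, 2)), rng.normal([8.0, 8.0], 1.0, (100, 2))]
    )
    return ek.EnsembleSnapshot(np.exp(logs), ["a", "b"])
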
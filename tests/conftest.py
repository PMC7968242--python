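import numpy as np
import pytest

from coexalign import PipelineConfig, compare_networks, make_topology


@pytest.fixture(scope="session")
def line_selfcmp():
    """Joint embedding of two copies of the 50-node line fixture.

    Shared across tests that only need *a* converged two-network
    comparison; seeded, so every consumer sees identical results.
    """
    net = make_topology("line", 50)
    return compare_networks(net, net.copy(), config=PipelineConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
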
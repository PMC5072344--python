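import numpy as np
import pytest

from boolscape.landscape import MarkerConfig, enumerate_landscape
from boolscape.network import apply_mutations, parse_bnet
from boolscape.synth import toy_colorectal_fixture


@pytest.fixture(scope="session")
def toy():
    """(network, markers, profile) of the colorectal-like 20-node model."""
    return toy_colorectal_fixture()


@pytest.fixture(scope="session")
def toy_landscapes(toy):
    """Exact landscapes of the toy model at mutation stages 0..4."""
    net, markers, profile = toy
    return [enumerate_landscape(apply_mutations(net, profile, s), markers)
            for s in range(len(profile) + 1)]


@pytest.fixture
def oscillator():
    """Two-node network whose only attractor is the 4-cycle
    (0,0)->(1,0)->(1,1)->(0,1)."""
    return parse_bnet("A, !B\nB, A\n")


def generic_markers(network):
    """Marker config over the first eight nodes, no input condition —
    enough to drive landscape machinery on networks without biology."""
    names = network.node_names
    if len(names) < 8:
        raise ValueError("need >= 8 nodes")
    return MarkerConfig(*names[:8])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
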
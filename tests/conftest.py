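import numpy as np
import pytest

from fibrasync import LocomotionNetwork, ModelParams, paper_toys
from fibrasync.synthetic_data import LiftSpec, locomotion_base, planted_lift


@pytest.fixture(scope="session")
def toys():
    return paper_toys()


@pytest.fixture(scope="session")
def locomotion():
    from fibrasync import locomotion_fixture

    return locomotion_fixture(seed=1)


@pytest.fixture
def lift_factory():
    """Planted lifts of a small identifiable chem base (fiber sizes 2,3,1)."""

    def make(seed=7, sizes=(2, 3, 1)):
        base = LocomotionNetwork()
        for v in "xyz":
            base.add_node(v)
        base.add_edge("x", "y", 2, "chem")
        base.add_edge("y", "z", 1, "chem")
        base.add_edge("z", "x", 1, "chem")
        base.add_edge("x", "x", 1, "chem")
        spec = LiftSpec(base, dict(zip("xyz", sizes)), seed=seed, identifiable=True)
        return planted_lift(spec)

    return make


@pytest.fixture
def isolated_neuron():
    net = LocomotionNetwork()
    net.add_node("solo")
    return net


@pytest.fixture
def chem_pair():
    """Two mutually excitatory neurons, unit chem weights."""
    net = LocomotionNetwork()
    net.add_node("a")
    net.add_node("b")
    net.add_edge("a", "b", 1, "chem")
    net.add_edge("b", "a", 1, "chem")
    return net
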
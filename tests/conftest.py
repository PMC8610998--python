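"""Shared geometric fixtures, all built in-memory from the fixture module."""

import numpy as np
import pytest

from mitonet.network_graph import LinearNetwork
from mitonet.synthetic import FixtureSpec, make_network, network_from_polylines

PIXEL_SIZE = 0.1  # um/px for hand-built test networks


@pytest.fixture
def segment_10um() -> LinearNetwork:
    """One straight 10 um segment."""
    return network_from_polylines([np.array([[1.0, 0.0], [1.0, 10.0]])], PIXEL_SIZE)


@pytest.fixture
def y_network() -> LinearNetwork:
    """Three 10 um arms meeting at one junction."""
    c = np.array([12.0, 12.0])
    arms = [np.array([c, c + [0.0, 10.0]]), np.array([c, c + [10.0, 0.0]]), np.array([c, c + [-10.0, 0.0]])]
    return network_from_polylines(arms, PIXEL_SIZE)


@pytest.fixture
def cycle_10um() -> LinearNetwork:
    """A closed loop of circumference 10 um (polygonal, 400 segments)."""
    r = 10.0 / (2 * np.pi)
    th = np.linspace(0, 2 * np.pi, 401)
    poly = np.stack([r + r * np.sin(th), r + r * np.cos(th)], axis=1)
    poly[-1] = poly[0]
    return network_from_polylines([poly], PIXEL_SIZE)


@pytest.fixture
def two_segment_network() -> LinearNetwork:
    """Two disjoint segments: 2 um and 1 um."""
    return network_from_polylines(
        [np.array([[1.0, 0.0], [1.0, 2.0]]), np.array([[4.0, 0.0], [4.0, 1.0]])], PIXEL_SIZE
    )


@pytest.fixture
def h_network() -> LinearNetwork:
    """H shape: two 10 um verticals bridged in the middle; J=2, E=4."""
    left = [np.array([[0.0, 0.0], [5.0, 0.0]]), np.array([[5.0, 0.0], [10.0, 0.0]])]
    right = [np.array([[0.0, 6.0], [5.0, 6.0]]), np.array([[5.0, 6.0], [10.0, 6.0]])]
    bridge = [np.array([[5.0, 0.0], [5.0, 6.0]])]
    return network_from_polylines(left + right + bridge, PIXEL_SIZE)


@pytest.fixture
def comb_network() -> LinearNetwork:
    """Branched connected fixture, ~500 um, pixel size 0.06."""
    return make_network(FixtureSpec(network_kind="tree", total_length_um=500.0, n_branches=16))


def random_tree(seed: int, n_nodes: int = 10, box: float = 30.0) -> LinearNetwork:
    """Small random spanning-tree network for oracle comparisons."""
    spec = FixtureSpec(network_kind="random_skeleton", n_nodes=n_nodes, box_um=box, seed=seed)
    return make_network(spec)
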
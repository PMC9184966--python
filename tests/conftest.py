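"""Shared fixtures: small graphs with hand-checkable structure."""

import numpy as np
import pytest

from linfra import build_graph, fixtures


@pytest.fixture
def two_cycle():
    """1 <-> 2 with symbolic rates a, b: the smallest reversible graph."""
    return build_graph(["1", "2"], [("1", "2", "a"), ("2", "1", "b")],
                       {"a": 2.0, "b": 1.0})


@pytest.fixture
def three_cycle_reversible():
    """Reversible triangle with distinct numeric labels (non-equilibrium
    for generic values)."""
    edges = [("1", "2", 1.0), ("2", "1", 2.0), ("2", "3", 0.5),
             ("3", "2", 1.5), ("3", "1", 2.5), ("1", "3", 0.7)]
    return build_graph(["1", "2", "3"], edges)


@pytest.fixture
def four_vertex_strong():
    """Strongly connected 4-vertex graph with 9 symbolic labels k1..k9,
    structured so removing the two edges out of vertex 1 disconnects it."""
    edges = [("1", "2", "k1"), ("1", "3", "k2"), ("2", "4", "k3"),
             ("3", "4", "k4"), ("4", "1", "k5"), ("2", "1", "k6"),
             ("3", "1", "k7"), ("4", "2", "k8"), ("4", "3", "k9")]
    return build_graph(["1", "2", "3", "4"], edges)


@pytest.fixture
def allosteric_square_numeric():
    params = {"k1": 1.3, "k2": 0.7, "k3": 2.1, "k4": 0.9,
              "k5": 1.7, "k6": 0.4, "k7": 1.1, "k8": 2.3}
    return fixtures.make_allosteric_square(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
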
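"""Shared fixtures: hand-built reference networks used across the suite."""

from dataclasses import dataclass, field

import pytest

from softnet.network import PhyloNetwork, parse_enewick

#: three taxa, one reticulation (tag #H1) with parents x and y and leaf child h
H1FIX_ENEWICK = "((a,(h)#H1)x,(#H1,b)y)r;"


@dataclass
class NamedNetwork:
    net: PhyloNetwork
    n: dict = field(default_factory=dict)  # name -> node id


@pytest.fixture
def h1fix() -> NamedNetwork:
    """The three-taxon one-reticulation network, built with known node ids."""
    net = PhyloNetwork()
    n = {}
    n["root"] = net.add_node()
    n["x"] = net.add_node()
    n["y"] = net.add_node()
    n["a"] = net.add_node("a")
    n["b"] = net.add_node("b")
    n["h"] = net.add_node("h")
    n["H1"] = net.add_node()
    for u, v in [
        ("root", "x"),
        ("root", "y"),
        ("x", "a"),
        ("x", "H1"),
        ("y", "H1"),
        ("y", "b"),
        ("H1", "h"),
    ]:
        net.add_edge(n[u], n[v])
    net.validate()
    return NamedNetwork(net=net, n=n)


@pytest.fixture
def fig1() -> NamedNetwork:
    """A nine-component network with five non-trivial tree components.

    The root component C_r = {r, a1, a2} is leafless but visible through its
    inner reticulations; C_r1 and C_r2 carry one leaf each and are visible but
    not exposed; C_r5 = {c1, c2} is exposed but not visible (all three
    reticulations right below it - r4, r7, r8 - are cross); C_r6 = {r4}
    degenerates to a reticulation member.  r7 has parents in C_r5, C_r2 and
    C_r (in-degree three).
    """
    net = PhyloNetwork()
    n = {}

    def add(name, label=None):
        n[name] = net.add_node(label)

    for name in ["r", "a1", "a2", "b1", "b2", "d1", "d2", "c1", "c2"]:
        add(name)
    add("leaf4", "leaf4")
    add("leaf5", "leaf5")
    for name in ["r1", "r2", "r3", "r4", "r5", "r6", "r7", "r8"]:
        add(name)
    for i in (1, 2, 3, 6):
        add("leaf%d" % i, "leaf%d" % i)
    edges = [
        ("r", "a1"), ("r", "a2"),
        ("a1", "r1"), ("a1", "r7"), ("a1", "r3"),
        ("a2", "r1"), ("a2", "r2"), ("a2", "r3"),
        ("r1", "b1"), ("b1", "b2"), ("b1", "r2"), ("b1", "r6"),
        ("b2", "leaf4"), ("b2", "r5"),
        ("r2", "d1"), ("d1", "d2"), ("d1", "r5"), ("d1", "r6"),
        ("d2", "leaf5"), ("d2", "r7"), ("d2", "r8"),
        ("r5", "c1"), ("c1", "c2"), ("c1", "r4"),
        ("c2", "r7"), ("c2", "r8"),
        ("r6", "r4"), ("r4", "leaf3"),
        ("r7", "leaf1"), ("r8", "leaf2"), ("r3", "leaf6"),
    ]
    for u, v in edges:
        net.add_edge(n[u], n[v])
    net.validate()
    return NamedNetwork(net=net, n=n)


@pytest.fixture
def cherry_tree() -> PhyloNetwork:
    return parse_enewick("((a,b),c);")
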
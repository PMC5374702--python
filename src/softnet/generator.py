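"""Seeded random networks, clusters and network pairs for simulation studies.

Networks are grown by the standard edge-pair hybridization scheme: a random
rooted binary tree on the requested leaves (sequential attachment to a
uniformly chosen edge), then one reticulation at a time by sampling an ordered
pair of distinct edges (e1, e2) whose connection preserves acyclicity,
subdividing both and adding an edge from the e1-subdivision to the
e2-subdivision (which becomes the new in-degree-2 node).  Repeated hits can
place reticulations above reticulations, so the ensemble contains arbitrary
networks - including non-reticulation-visible ones - rather than any
restricted class.  In multi-combining mode additional in-edges are aimed at
existing reticulation nodes, producing in-degrees above two while keeping the
reticulation count exact.

Everything is driven by a single integer seed: the same GenSpec always yields
a byte-identical eNewick serialization.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Iterator

import networkx as nx

from .errors import GenerationError
from .network import PhyloNetwork

__all__ = ["GenSpec", "random_network", "random_cluster", "random_pair_stream"]

_MAX_TRIES_PER_RET = 200


@dataclass(frozen=True)
class GenSpec:
    """Parameters of one random draw.

    n_leaves:          number of labelled leaves (taxa t1..tn), >= 2
    n_reticulations:   exact number of in-degree->=2 nodes, >= 0
    bi_combining:      every reticulation keeps exactly two parents
    seed:              integer driving all randomness
    extra_in_edges:    in multi-combining mode, how many additional in-edges
                       to aim at existing reticulations (default: half the
                       reticulation count, at least one)
    """

    n_leaves: int
    n_reticulations: int = 0
    bi_combining: bool = True
    seed: int = 0
    extra_in_edges: int | None = None

    def __post_init__(self):
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if self.n_reticulations < 0:
            raise ValueError("n_reticulations must be >= 0")


def _random_binary_tree(net: PhyloNetwork, n: int, rng: random.Random) -> list:
    root = net.add_node()
    a = net.add_node("t1")
    b = net.add_node("t2")
    net.add_edge(root, a)
    net.add_edge(root, b)
    edges = [(root, a), (root, b)]
    for i in range(3, n + 1):
        x, y = edges.pop(rng.randrange(len(edges)))
        net.graph.remove_edge(x, y)
        mid = net.add_node()
        leaf = net.add_node("t%d" % i)
        net.add_edge(x, mid)
        net.add_edge(mid, y)
        net.add_edge(mid, leaf)
        edges.extend([(x, mid), (mid, y), (mid, leaf)])
    return edges


def _reaches(g: nx.DiGraph, src: int, dst: int) -> bool:
    return src == dst or nx.has_path(g, src, dst)


def random_network(spec: GenSpec) -> PhyloNetwork:
    """Draw one network with exactly the requested leaf/reticulation counts."""
    rng = random.Random(spec.seed)
    net = PhyloNetwork()
    edges = _random_binary_tree(net, spec.n_leaves, rng)
    g = net.graph

    for _ in range(spec.n_reticulations):
        for _attempt in range(_MAX_TRIES_PER_RET):
            i = rng.randrange(len(edges))
            j = rng.randrange(len(edges))
            if i == j:
                continue
            x1, y1 = edges[i]
            x2, y2 = edges[j]
            if _reaches(g, y2, x1):
                continue  # the new edge would close a cycle
            u = net.add_node()
            w = net.add_node()
            g.remove_edge(x1, y1)
            g.remove_edge(x2, y2)
            g.add_edge(x1, u)
            g.add_edge(u, y1)
            g.add_edge(x2, w)
            g.add_edge(w, y2)
            g.add_edge(u, w)  # w now has in-degree 2
            edges[i] = (x1, u)
            edges[j] = (x2, w)
            edges.extend([(u, y1), (w, y2), (u, w)])
            break
        else:
            raise GenerationError(
                "could not place a reticulation after %d attempts"
                % _MAX_TRIES_PER_RET
            )

    if not spec.bi_combining and spec.n_reticulations:
        extra = spec.extra_in_edges
        if extra is None:
            extra = max(1, spec.n_reticulations // 2)
        rets = sorted(v for v in g if g.in_degree(v) >= 2)
        for _ in range(extra):
            for _attempt in range(_MAX_TRIES_PER_RET):
                w = rets[rng.randrange(len(rets))]
                i = rng.randrange(len(edges))
                x1, y1 = edges[i]
                if w in (x1, y1) or g.has_edge(x1, w) or _reaches(g, w, x1):
                    continue
                u = net.add_node()
                g.remove_edge(x1, y1)
                g.add_edge(x1, u)
                g.add_edge(u, y1)
                g.add_edge(u, w)
                edges[i] = (x1, u)
                edges.extend([(u, y1)])
                break
            else:
                raise GenerationError("could not add an extra in-edge")

    net.validate()
    return net


def random_cluster(X, size_range, rng_or_seed) -> frozenset:
    """A uniform cluster: uniform size from ``size_range``, then a uniform
    subset of that size.  Sizes must lie in [1, |X|-1]."""
    labels = sorted(X)
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    sizes = sorted(set(size_range))
    if not sizes:
        raise ValueError("empty size range")
    if sizes[0] < 1 or sizes[-1] > len(labels) - 1:
        raise ValueError("cluster sizes must be between 1 and |X|-1")
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, random.Random)
        else random.Random(rng_or_seed)
    )
    k = sizes[rng.randrange(len(sizes))]
    return frozenset(rng.sample(labels, k))


def random_pair_stream(
    spec: GenSpec, n_pairs: int, seed: int
) -> Iterator[tuple[PhyloNetwork, PhyloNetwork]]:
    """Independent network pairs over a shared taxon set, reproducibly seeded."""
    master = random.Random(seed)
    for _ in range(n_pairs):
        s1 = master.randrange(2**31)
        s2 = master.randrange(2**31)
        yield (
            random_network(replace(spec, seed=s1)),
            random_network(replace(spec, seed=s2)),
        )
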
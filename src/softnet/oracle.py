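"""Brute-force ground truth: displayed-tree enumeration and the naive CCP/SRF.

A tree is displayed in a network when it results from keeping one incoming
edge per reticulation node, deleting the nodes that lie on no root-to-leaf
path, and contracting the degree-two nodes.  Enumerating all prod(indeg(r))
parent choices therefore solves the CCP naively, and collecting the clusters
of the (deduplicated) displayed trees of two networks gives the SRF distance
the way Dendroscope computes it.  These routines are exponential by design:
they serve as the independent oracle the decomposition solver is validated
against, and as an alternative backend for small networks.
"""

from __future__ import annotations

import itertools
import logging
from fractions import Fraction
from typing import Iterator

import networkx as nx

from .errors import GuardError, TaxonMismatchError
from .network import PhyloNetwork

__all__ = [
    "displayed_trees",
    "displayed_tree_set",
    "tree_contains_cluster",
    "naive_ccp",
    "naive_soft_cluster_set",
    "naive_srf",
]

log = logging.getLogger(__name__)

#: refuse to enumerate parent choices above this many reticulations
RETICULATION_GUARD = 20


def _parent_choices(net: PhyloNetwork, force: bool) -> Iterator[dict[int, int]]:
    rets = sorted(net.reticulations)
    if len(rets) > RETICULATION_GUARD and not force:
        raise GuardError(
            "%d reticulation nodes exceed the enumeration guard (%d); "
            "pass force=True to override" % (len(rets), RETICULATION_GUARD)
        )
    parent_lists = [sorted(net.parents(r)) for r in rets]
    for combo in itertools.product(*parent_lists):
        yield dict(zip(rets, combo))


def _chosen_graph(net: PhyloNetwork, choice: dict[int, int]) -> nx.DiGraph:
    g = net.graph
    out = nx.DiGraph()
    out.add_nodes_from(g.nodes(data=True))
    for v in g:
        preds = list(g.predecessors(v))
        if v in choice:
            out.add_edge(choice[v], v)
        else:
            for u in preds:
                out.add_edge(u, v)
    return out


def _extract_tree(net: PhyloNetwork, choice: dict[int, int]) -> PhyloNetwork:
    """Apply a parent choice, prune off-path nodes, contract degree-two nodes."""
    g = _chosen_graph(net, choice)
    root = net.root
    labels = net.leaf_labels
    reachable = {root} | nx.descendants(g, root)
    useful = {v for v in labels if v in reachable}
    stack = list(useful)
    while stack:
        for u in g.predecessors(stack.pop()):
            if u in reachable and u not in useful:
                useful.add(u)
                stack.append(u)
    g.remove_nodes_from(set(g) - useful)
    # contract degree-two nodes (in-degree one, out-degree one)
    for v in list(g):
        if g.in_degree(v) == 1 and g.out_degree(v) == 1 and v not in labels:
            (u,) = g.predecessors(v)
            (w,) = g.successors(v)
            g.remove_node(v)
            g.add_edge(u, w)
    # suppress a chain of out-degree-one roots
    while True:
        roots = [v for v in g if g.in_degree(v) == 0]
        if len(roots) == 1 and g.out_degree(roots[0]) == 1 and roots[0] not in labels:
            g.remove_node(roots[0])
        else:
            break
    tree = PhyloNetwork.__new__(PhyloNetwork)
    tree.graph = g
    tree._next_id = (max(g) + 1) if len(g) else 0
    return tree


def displayed_trees(
    net: PhyloNetwork, force: bool = False
) -> Iterator[tuple[dict[int, int], PhyloNetwork]]:
    """Yield every (parent choice, extracted tree) pair, without deduplication.

    Exactly prod over reticulations r of indeg(r) pairs are produced (2^|R|
    for a bi-combining network); distinct choices may yield equal trees.
    """
    for choice in _parent_choices(net, force):
        yield choice, _extract_tree(net, choice)


def canonical_newick(tree: PhyloNetwork) -> str:
    """Order-independent serialization used to deduplicate displayed trees."""
    g = tree.graph
    labels = tree.leaf_labels

    def fmt(v: int) -> str:
        kids = list(g.successors(v))
        if not kids:
            return labels.get(v, "")
        return "(" + ",".join(sorted(fmt(k) for k in kids)) + ")"

    return fmt(tree.root) + ";"


def displayed_tree_set(
    net: PhyloNetwork, force: bool = False
) -> list[PhyloNetwork]:
    """Deduplicated displayed trees over the full taxon set.

    A parent choice that strands part of the taxon set (possible only in
    networks with dummy debris) yields a tree over a smaller label set, which
    is not displayed by definition; such trees are logged and excluded.
    """
    X = net.X
    seen: dict[str, PhyloNetwork] = {}
    for _, tree in displayed_trees(net, force=force):
        if tree.X != X:
            log.debug(
                "excluding displayed candidate over %d/%d taxa",
                len(tree.X),
                len(X),
            )
            continue
        seen.setdefault(canonical_newick(tree), tree)
    return list(seen.values())


def _clusters_of_graph(g: nx.DiGraph, labels: dict[int, str]):
    """Leaf-label set below every node, bottom-up; proper nonempty ones."""
    below: dict[int, frozenset[str]] = {}
    for v in reversed(list(nx.topological_sort(g))):
        s = set()
        if v in labels:
            s.add(labels[v])
        for w in g.successors(v):
            s |= below[w]
        below[v] = frozenset(s)
    X = frozenset(labels.values())
    return {s for s in below.values() if s and s != X}


def tree_contains_cluster(tree: PhyloNetwork, B) -> bool:
    """True iff some node of the tree has leaf set exactly B (one bottom-up pass)."""
    B = frozenset(B)
    return B in _clusters_of_graph(tree.graph, tree.leaf_labels)


def naive_ccp(net: PhyloNetwork, B, force: bool = False) -> bool:
    """CCP by displayed-tree enumeration; short-circuits on the first hit.

    Contraction and off-path pruning never change the nonempty clusters of a
    parent-choice subgraph, so the check runs directly on the chosen graph.
    """
    B = frozenset(B)
    X = net.X
    labels = net.leaf_labels
    for choice in _parent_choices(net, force):
        g = _chosen_graph(net, choice)
        root = net.root
        reach = {root} | nx.descendants(g, root)
        if {labels[v] for v in reach if v in labels} != X:
            continue  # not a tree over X
        sub = g.subgraph(reach)
        if B in _clusters_of_graph(sub, {v: labels[v] for v in reach if v in labels}):
            return True
    return False


def naive_soft_cluster_set(net: PhyloNetwork, force: bool = False) -> frozenset:
    """All soft clusters, collected from the deduplicated displayed trees."""
    out: set[frozenset[str]] = set()
    for tree in displayed_tree_set(net, force=force):
        out |= _clusters_of_graph(tree.graph, tree.leaf_labels)
    return frozenset(out)


def naive_srf(net1: PhyloNetwork, net2: PhyloNetwork, force: bool = False):
    """SRF distance via displayed-tree enumeration on both networks.

    Returns a DistanceReport; equals distances.srf_distance on every pair.
    """
    from .distances import DistanceReport

    if net1.X != net2.X:
        raise TaxonMismatchError(net1.X - net2.X, net2.X - net1.X)
    s1 = naive_soft_cluster_set(net1, force=force)
    s2 = naive_soft_cluster_set(net2, force=force)
    left = len(s1 - s2)
    right = len(s2 - s1)
    return DistanceReport(
        value=Fraction(left + right, 2),
        left_only=left,
        right_only=right,
        kind="SRF",
    )
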
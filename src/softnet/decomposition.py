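"""Tree-component decomposition of a rooted phylogenetic network.

Removing the reticulation nodes from a network leaves a forest: there is one
tree component C_r for every r in R(N) u {rho(N)}, namely the maximal set of
tree nodes and leaves reachable from r (from the child side, for a
reticulation) without crossing another reticulation node.  When the child c(r)
is itself a reticulation the component degenerates to {c(r)}, and when r has no
child (a dummy reticulation produced by edge surgery) the component is empty.

A component is *trivial* if it is empty or consists of a single leaf.  A
reticulation r' (and its component) is *right below* C_r if some parent of r'
lies in C_r.  C_r is *exposed* when every component right below it is trivial,
and *visible* when some leaf l exists such that every root-to-l path meets the
component.  For exposed components visibility has the exact combinatorial
characterisation implemented by :func:`component_visibility`: C_r is visible
iff it contains a leaf or some reticulation right below it has all its parents
inside C_r (an inner reticulation).

The containment solver drives its reductions off the sets

    L_r      = { c(r') : r' inner }  u  leaves(C_r)      (leaves C_r is visible on)
    Lcheck_r = { c(r') : r' cross, c(r') in B }          (B-leaves it is not visible on)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import ContractError
from .network import PhyloNetwork

__all__ = [
    "TreeComponent",
    "tree_components",
    "right_below",
    "is_exposed",
    "is_visible_on",
    "component_visibility",
    "inner_cross",
    "leaves_L",
    "leaves_Lcheck",
    "leaf_below_reticulation",
]


@dataclass(frozen=True)
class TreeComponent:
    """One tree component C_r of the decomposition.

    ``root_tag`` is the reticulation node r (or the network root) the component
    belongs to; ``head`` is the component's top node rho(C_r) (c(r) for a
    reticulation tag, the root itself for the root component; None when empty).
    """

    root_tag: int
    head: int | None
    members: frozenset[int]
    leaf_members: frozenset[int]
    is_trivial: bool
    is_exposed: bool
    is_visible: bool
    is_degenerate: bool = field(compare=False, default=False)
    below_all_trivial: bool = field(compare=False, default=False)


def _boundaries(net: PhyloNetwork) -> set[int]:
    return {v for v, p in net.graph._pred.items() if len(p) >= 2}


def _component_members(net: PhyloNetwork, tag: int, bnd: set[int]) -> tuple[int | None, frozenset[int]]:
    g = net.graph
    if tag in bnd:
        kids = list(g._succ[tag])
        if not kids:
            return None, frozenset()  # dummy reticulation: empty component
        head = kids[0]
        if head in bnd:
            return head, frozenset({head})
    else:
        head = tag  # the network root
    succ = g._succ
    stack, members = [head], {head}
    while stack:
        for w in succ[stack.pop()]:
            if w not in bnd and w not in members:
                members.add(w)
                stack.append(w)
    return head, frozenset(members)


def tree_components(net: PhyloNetwork) -> dict[int, TreeComponent]:
    """Decompose ``net``: one component per reticulation node plus the root's.

    The non-empty member sets are pairwise disjoint and, together, cover every
    tree node and leaf of the network (degenerate {c(r)} components coincide
    with no tree node or leaf).
    """
    g = net.graph
    bnd = _boundaries(net)
    labels = net.leaf_labels
    tags = sorted(bnd) + [net.root]

    raw: dict[int, tuple[int | None, frozenset[int]]] = {
        tag: _component_members(net, tag, bnd) for tag in tags
    }
    member_sets = {tag: m for tag, (_, m) in raw.items()}

    succ = g._succ
    rb: dict[int, set[int]] = {}
    for tag, members in member_sets.items():
        below = set()
        for v in members:
            for w in succ[v]:
                if w in bnd:
                    below.add(w)
        rb[tag] = below

    trivial: dict[int, bool] = {}
    degenerate: dict[int, bool] = {}
    for tag, members in member_sets.items():
        degenerate[tag] = bool(members) and next(iter(members)) in bnd
        n_leaves = sum(1 for v in members if v in labels)
        # Trivial: empty, or a chain carrying at most one leaf and separating
        # nothing below it.  The degenerate {c(r)} reticulation member and any
        # component with reticulations right below stay non-trivial.
        trivial[tag] = not members or (
            not degenerate[tag] and not rb[tag] and n_leaves <= 1
        )

    comps: dict[int, TreeComponent] = {}
    for tag in tags:
        head, members = raw[tag]
        leaf_members = frozenset(v for v in members if v in labels)
        below_all_trivial = all(trivial[b] for b in rb[tag])
        # a component that is itself a single-leaf chain has nothing right
        # below it, so "contains only one leaf" is subsumed by this condition
        exposed = below_all_trivial
        # inner reticulation right below, with a leaf to witness visibility
        inner_with_leaf = any(
            set(g._pred[b]) <= members
            and leaf_below_reticulation(net, b) is not None
            for b in rb[tag]
        )
        visible = bool(leaf_members) or inner_with_leaf
        comps[tag] = TreeComponent(
            root_tag=tag,
            head=head,
            members=members,
            leaf_members=leaf_members,
            is_trivial=trivial[tag],
            is_exposed=exposed,
            is_visible=visible,
            is_degenerate=degenerate[tag],
            below_all_trivial=below_all_trivial,
        )
    return comps


def right_below(net: PhyloNetwork, comp: TreeComponent) -> set[int]:
    """Reticulation nodes with at least one parent inside ``comp``."""
    g = net.graph
    bnd = _boundaries(net)
    out = set()
    for v in comp.members:
        for w in g.successors(v):
            if w in bnd:
                out.add(w)
    return out


def is_exposed(net: PhyloNetwork, comp: TreeComponent) -> bool:
    """True iff every component right below ``comp`` is trivial.

    A component that consists of a single leaf has nothing right below it and
    is therefore exposed by vacuity.
    """
    comps = tree_components(net)
    return all(comps[b].is_trivial for b in right_below(net, comp))


def is_visible_on(net: PhyloNetwork, v: int, taxon: str) -> bool:
    """True iff every directed root-to-``taxon`` path passes through ``v``.

    Computed exactly by removal: v is visible on the leaf iff the leaf becomes
    unreachable from the root in N - {v}.
    """
    leaf = net.leaf_with_label(taxon)
    if v == leaf:
        return True
    root = net.root
    if v == root:
        return True
    g = net.graph.copy()
    g.remove_node(v)
    return not nx.has_path(g, root, leaf)


def component_visibility(
    net: PhyloNetwork,
    comp: TreeComponent,
    IR: set[int],
    component_leaves: frozenset[str] | set[str],
) -> bool:
    """Exact visibility test for an *exposed* component.

    C_r is visible iff it contains a leaf or an inner reticulation with a leaf
    child exists right below it.  The characterisation is stated for exposed
    components only; calling it on a non-exposed one is a contract error.
    """
    if not is_exposed(net, comp):
        raise ContractError(
            "component_visibility is only defined for exposed components"
        )
    if component_leaves:
        return True
    return any(leaf_below_reticulation(net, r) is not None for r in IR)


def inner_cross(net: PhyloNetwork, comp: TreeComponent) -> tuple[set[int], set[int]]:
    """Split the reticulations right below ``comp`` into inner and cross sets.

    Inner reticulations have *all* parents inside the component; cross
    reticulations have at least one parent elsewhere.
    """
    g = net.graph
    IR, CR = set(), set()
    for r in right_below(net, comp):
        if set(g.predecessors(r)) <= comp.members:
            IR.add(r)
        else:
            CR.add(r)
    return IR, CR


def leaf_below_reticulation(net: PhyloNetwork, r: int) -> str | None:
    """The taxon at the end of the single-child chain under ``r``, if any.

    For a reticulation right below an exposed component the chain is a direct
    leaf child; dummy reticulations (no leaf) yield None and are skipped by the
    L_r / Lcheck_r formulas.
    """
    g = net.graph
    v = r
    seen = {v}
    while True:
        kids = list(g._succ[v])
        if not kids:
            lab = net.label_of(v)
            return lab  # None for a dummy
        if len(kids) > 1:
            return None
        v = kids[0]
        if v in seen:  # defensive; validated networks are acyclic
            return None
        seen.add(v)


def leaves_L(net: PhyloNetwork, comp: TreeComponent, IR: set[int]) -> frozenset[str]:
    """L_r: the leaves on which ``comp`` is visible.

    Union of the component's own leaf labels and the leaf children of its
    inner reticulations.
    """
    labels = net.leaf_labels
    out = {labels[v] for v in comp.leaf_members}
    for r in IR:
        lab = leaf_below_reticulation(net, r)
        if lab is not None:
            out.add(lab)
    return frozenset(out)


def leaves_Lcheck(
    net: PhyloNetwork,
    comp: TreeComponent,
    CR: set[int],
    B: frozenset[str] | set[str],
) -> frozenset[str]:
    """Lcheck_r: leaf children of cross reticulations that belong to B."""
    out = set()
    for r in CR:
        lab = leaf_below_reticulation(net, r)
        if lab is not None and lab in B:
            out.add(lab)
    return frozenset(out)
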
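"""Decomposition-based solver for the cluster containment problem (CCP).

Given a rooted phylogenetic network N over taxa X and a cluster B (a proper
nonempty subset of X), the CCP asks whether B is a *soft* cluster of N, i.e.
whether some tree displayed in N has a node whose leaf set is exactly B.  The
problem is NP-complete on arbitrary networks; this solver recursively shrinks
the instance through the tree-component decomposition:

* It selects a non-trivial component C_r whose right-below components are all
  trivial.  If C_r is visible (it carries a leaf, or an inner reticulation with
  a leaf child), a single linear in-component check decides whether B is a soft
  cluster *at a node of C_r*; on failure the instance either resolves (when the
  visible leaves L_r straddle B and its complement) or reduces to one strictly
  smaller instance by collapsing C_r to a single leaf after retargeting the
  cross reticulations below it (the caseA / caseB reductions).
* If C_r is not visible, a cross reticulation below it is resolved both ways:
  keep only its in-edges from inside C_r, or only those from outside, and the
  answer is the disjunction of the two sub-instances (the non-visible split).

The number m of in-component checks executed over the whole recursion is the
empirical hardness of the instance; b(N, B) = log2(m) is the *effective
reticulation number*.  The naive alternative inspects all prod(indeg(r))
displayed trees, so b(N, B) < |R(N)| means the decomposition search space is
smaller than the naive one.

A YES answer carries a witness: a node v and a reticulation->parent map such
that, keeping exactly the chosen in-edge at every reticulation of the original
network, the labelled leaves reachable from v are exactly B.  Witnesses are
lifted back through every reduction, so they always refer to the input network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .decomposition import (
    TreeComponent,
    inner_cross,
    leaf_below_reticulation,
    leaves_L,
    leaves_Lcheck,
    right_below,
    tree_components,
)
from .errors import ContractError
from .network import PhyloNetwork, descendants_of

__all__ = [
    "ANSWER_YES",
    "CCPResult",
    "Witness",
    "component_contains",
    "reduce_visible_caseA",
    "reduce_visible_caseB",
    "split_nonvisible",
    "ccp_solve",
    "verify_witness",
    "effective_reticulation_number",
    "max_effective_reticulation_number",
]


class _AnswerYes:
    def __repr__(self) -> str:
        return "ANSWER_YES"


#: Sentinel returned by :func:`reduce_visible_caseA` when B-hat == B resolves
#: the instance positively without any further recursion.
ANSWER_YES = _AnswerYes()


@dataclass(frozen=True)
class Witness:
    """Proof of a YES answer, valid in the original input network."""

    node: int
    choices: dict[int, int] = field(compare=False, default_factory=dict)
    component_root: int | None = None


@dataclass(frozen=True)
class CCPResult:
    answer: bool
    m: int
    b: float
    witness: Witness | None = None


# ---------------------------------------------------------------------------
# housekeeping
# ---------------------------------------------------------------------------


def _tidy(net: PhyloNetwork) -> PhyloNetwork:
    """Drop nodes unreachable from the root or with no labelled leaf below.

    Neither kind of node can occur in any displayed tree over the full taxon
    set, so the soft-cluster set is unchanged; reductions and edge deletions
    may leave such debris behind.
    """
    g = net.graph
    root = net.root
    reachable = {root} | descendants_of(g, root)
    labelled = [v for v, d in g._node.items() if "label" in d]
    useful = set(labelled)
    stack = list(labelled)
    pred = g._pred
    while stack:
        for u in pred[stack.pop()]:
            if u not in useful:
                useful.add(u)
                stack.append(u)
    keep = reachable & useful
    if len(keep) == len(g):
        return net
    out = net.copy()
    out.graph.remove_nodes_from(set(g) - keep)
    return out


def _any_parent(net: PhyloNetwork, r: int) -> int:
    return min(net.parents(r))


# ---------------------------------------------------------------------------
# the in-component containment check (Step 3)
# ---------------------------------------------------------------------------


def _component_check(
    net: PhyloNetwork, comp: TreeComponent, B: frozenset[str]
) -> tuple[bool, int | None, dict[int, int] | None]:
    """Decide whether B is a soft cluster at some node of ``comp``.

    Only parent choices at the reticulations right below the component are
    involved (everything deeper is a plain leaf because the component is
    exposed).  For each node v the taxa below it split into mandatory ones
    (component leaves under v, and leaf children of reticulations all of whose
    parents lie under v) and optional ones (leaf children of reticulations
    with parents both under and not under v); B is a soft cluster at v iff
    mandatory(v) <= B <= mandatory(v) | optional(v).

    Returns (answer, witness node, parent choices for the right-below
    reticulations realising B at that node).
    """
    g = net.graph
    labels = net.leaf_labels
    members = comp.members
    rb = sorted(right_below(net, comp))
    ret_leaf = {r: leaf_below_reticulation(net, r) for r in rb}
    taxa = sorted(
        {labels[v] for v in comp.leaf_members}
        | {lab for lab in ret_leaf.values() if lab is not None}
    )
    if not B <= set(taxa):
        return False, None, None
    bit = {lab: 1 << i for i, lab in enumerate(taxa)}
    Bm = 0
    for lab in B:
        Bm |= bit[lab]
    indeg = {r: g.in_degree(r) for r in rb}

    # iterative post-order over the component's internal tree structure
    order: list[int] = []
    stack = [comp.head]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in g.successors(v):
            if w in members:
                stack.append(w)
    leafmask: dict[int, int] = {}
    cnt: dict[int, dict[int, int]] = {}
    for v in reversed(order):
        lm = bit[labels[v]] if v in labels else 0
        c: dict[int, int] = {}
        for w in g.successors(v):
            if w in members:
                lm |= leafmask[w]
                for r, k in cnt[w].items():
                    c[r] = c.get(r, 0) + k
            elif w in indeg:
                c[w] = c.get(w, 0) + 1
        leafmask[v] = lm
        cnt[v] = c
        mand = lm
        opt = 0
        for r, k in c.items():
            if ret_leaf[r] is None:
                continue
            rbit = bit[ret_leaf[r]]
            if k == indeg[r]:
                mand |= rbit
            else:
                opt |= rbit
        if mand & ~Bm == 0 and Bm & ~(mand | opt) == 0:
            choices = _check_witness_choices(net, comp, B, v, rb, ret_leaf)
            return True, v, choices
    return False, None, None


def _check_witness_choices(net, comp, B, v, rb, ret_leaf):
    """Parent choices at the right-below reticulations realising B at v."""
    g = net.graph
    under = {v}
    stack = [v]
    while stack:
        u = stack.pop()
        for w in g.successors(u):
            if w in comp.members and w not in under:
                under.add(w)
                stack.append(w)
    choices: dict[int, int] = {}
    for r in rb:
        parents = sorted(g.predecessors(r))
        lab = ret_leaf[r]
        if lab is not None and lab in B:
            below = [p for p in parents if p in under]
            choices[r] = below[0]
        else:
            away = [p for p in parents if p not in under]
            choices[r] = away[0] if away else parents[0]
    return choices


def component_contains(
    net: PhyloNetwork, comp: TreeComponent, B
) -> tuple[bool, int | None]:
    """Public in-component check; see :func:`_component_check`.

    Precondition: ``comp`` is non-trivial and every component right below it is
    trivial (it is exposed).
    """
    comps = tree_components(net)
    if comp.is_trivial:
        raise ContractError("component_contains requires a non-trivial component")
    if not all(comps[r].is_trivial for r in right_below(net, comp)):
        raise ContractError(
            "component_contains requires all right-below components trivial"
        )
    ok, v, _ = _component_check(net, comp, frozenset(B))
    return ok, v


# ---------------------------------------------------------------------------
# reductions (Theorem 1) and the non-visible split
# ---------------------------------------------------------------------------


def reduce_visible_caseA(
    net: PhyloNetwork,
    comp: TreeComponent,
    B: frozenset[str],
    IR: set[int],
    CR: set[int],
    L_r: frozenset[str],
    Lcheck_r: frozenset[str],
):
    """Visible-component reduction for L_r <= B.

    Retarget every cross reticulation below the component (keep its inside
    parents when its leaf is in B, its outside parents otherwise), giving N_a.
    The leaves below the component's head in N_a are exactly
    B-hat = L_r | Lcheck_r <= B.  If B-hat == B the answer is YES; otherwise
    the component is collapsed to the single leaf l = min(L_r) and the
    instance becomes (B' , N_a') with B' = (B \\ B-hat) | {l}.
    """
    if not L_r:
        raise ContractError("caseA requires a visible component (L_r nonempty)")
    if not L_r <= B:
        raise ContractError("caseA requires L_r to be a subset of B")
    dels = []
    for r in CR:
        lab = leaf_below_reticulation(net, r)
        in_b = lab is not None and lab in B
        for u in net.parents(r):
            if (u in comp.members) != in_b:
                dels.append((u, r))
    net_a = net.delete_edges(dels)
    b_hat = frozenset(L_r | Lcheck_r)
    if b_hat == B:
        return ANSWER_YES
    ell = min(L_r)
    net_a_prime = net_a.replace_below(comp.head, ell)
    b_prime = frozenset(B - b_hat) | {ell}
    return b_prime, net_a_prime


def reduce_visible_caseB(
    net: PhyloNetwork, comp: TreeComponent, B: frozenset[str], CR: set[int]
) -> PhyloNetwork:
    """Visible-component reduction for L_r disjoint from B.

    Retarget the cross reticulations the opposite way (keep outside parents
    for leaves not in B, inside parents for leaves in B), then collapse the
    component to a single leaf l = min(L_r); since L_r and B are disjoint,
    l is not in B and B itself is unchanged.
    """
    IR, _ = inner_cross(net, comp)
    L_r = leaves_L(net, comp, IR)
    if not L_r:
        raise ContractError("caseB requires a visible component (L_r nonempty)")
    if L_r & B:
        raise ContractError("caseB requires L_r disjoint from B")
    dels = []
    for r in CR:
        lab = leaf_below_reticulation(net, r)
        in_b = lab is not None and lab in B
        for u in net.parents(r):
            if (u in comp.members) == in_b:
                dels.append((u, r))
    net_b = net.delete_edges(dels)
    ell = min(L_r)
    return net_b.replace_below(comp.head, ell)


def _split_choice(net: PhyloNetwork, comp: TreeComponent):
    """Pick the reticulation the non-visible split resolves, plus edge sets."""
    if comp.is_degenerate:
        rp = comp.head
        tag = comp.root_tag
        inside = [(u, rp) for u in net.parents(rp) if u == tag]
        outside = [(u, rp) for u in net.parents(rp) if u != tag]
    else:
        _, CR = inner_cross(net, comp)
        eligible = sorted(
            r
            for r in CR
            if any(u not in comp.members for u in net.parents(r))
        )
        if not eligible:
            raise ContractError(
                "split requires a cross reticulation with an outside parent"
            )
        rp = eligible[0]
        inside = [(u, rp) for u in net.parents(rp) if u in comp.members]
        outside = [(u, rp) for u in net.parents(rp) if u not in comp.members]
    if not outside or not inside:
        raise ContractError("split reticulation must have parents on both sides")
    return rp, inside, outside


def split_nonvisible(
    net: PhyloNetwork, comp: TreeComponent
) -> tuple[PhyloNetwork, PhyloNetwork]:
    """Resolve one cross reticulation below a non-visible component both ways.

    Returns (N', N''): N' keeps only the in-edges from inside the component,
    N'' keeps only those from outside.  B is a soft cluster of N iff it is a
    soft cluster of N' or of N''.
    """
    if not comp.is_degenerate:
        IR, _ = inner_cross(net, comp)
        if leaves_L(net, comp, IR):
            raise ContractError("split requires a non-visible component")
    rp, inside, outside = _split_choice(net, comp)
    return net.delete_edges(outside), net.delete_edges(inside)


# ---------------------------------------------------------------------------
# the recursive solver
# ---------------------------------------------------------------------------


def _select_component(comps: dict[int, TreeComponent]) -> TreeComponent:
    cands = [
        c for c in comps.values() if not c.is_trivial and c.below_all_trivial
    ]
    if not cands:
        raise ContractError(
            "no selectable tree component; network not in solver form"
        )
    # prefer a visible component, then the smallest, ties by identifier
    return min(cands, key=lambda c: (not c.is_visible, len(c.members), c.root_tag))


def _solve(net, B, counter, trace, want_witness):
    net = _tidy(net)

    if len(B) == 1:
        (lab,) = B
        if not want_witness:
            return True, None
        return True, (net.leaf_with_label(lab), {})

    comps = tree_components(net)
    comp = _select_component(comps)

    if comp.is_degenerate:
        return _do_split(net, comp, B, counter, trace, want_witness)

    IR, CR = inner_cross(net, comp)
    L_r = leaves_L(net, comp, IR)
    if not L_r:
        return _do_split(net, comp, B, counter, trace, want_witness)

    counter[0] += 1
    ok, v, rb_choices = _component_check(net, comp, B)
    if ok:
        if not want_witness:
            return True, None
        choices = dict(rb_choices)
        for r in net.reticulations:
            choices.setdefault(r, _any_parent(net, r))
        return True, (v, choices)

    in_b = L_r & B
    out_b = L_r - B
    if in_b and out_b:
        # B straddles the leaves the component is visible on: had B been a
        # soft cluster of N it would have been one at a node of C_r.
        return False, None

    if not out_b:  # L_r <= B : caseA
        Lcheck = leaves_Lcheck(net, comp, CR, B)
        res = reduce_visible_caseA(net, comp, B, IR, CR, L_r, Lcheck)
        if res is ANSWER_YES:
            if trace is not None:
                trace.append(
                    {"kind": "caseA_yes", "parent": (net, B), "children": []}
                )
            if not want_witness:
                return True, None
            choices = _region_choices(net, comp, B, IR, CR, keep_inside_for_b=True)
            for r in net.reticulations:
                choices.setdefault(r, _any_parent(net, r))
            return True, (comp.head, choices)
        b_prime, net_a_prime = res
        if trace is not None:
            trace.append(
                {
                    "kind": "caseA",
                    "parent": (net, B),
                    "children": [(net_a_prime, b_prime)],
                }
            )
        sub, wit = _solve(net_a_prime, b_prime, counter, trace, want_witness)
        if not sub:
            return False, None
        if not want_witness:
            return True, None
        return True, _lift_collapse(net, comp, B, IR, CR, wit, keep_inside_for_b=True)

    # L_r disjoint from B : caseB
    net_b_prime = reduce_visible_caseB(net, comp, B, CR)
    if trace is not None:
        trace.append(
            {"kind": "caseB", "parent": (net, B), "children": [(net_b_prime, B)]}
        )
    sub, wit = _solve(net_b_prime, B, counter, trace, want_witness)
    if not sub:
        return False, None
    if not want_witness:
        return True, None
    return True, _lift_collapse(net, comp, B, IR, CR, wit, keep_inside_for_b=False)


def _do_split(net, comp, B, counter, trace, want_witness):
    rp, inside, outside = _split_choice(net, comp)
    n1 = net.delete_edges(outside)
    n2 = net.delete_edges(inside)
    if trace is not None:
        trace.append(
            {"kind": "split", "parent": (net, B), "children": [(n1, B), (n2, B)]}
        )
    for branch in (n1, n2):
        sub, wit = _solve(branch, B, counter, trace, want_witness)
        if sub:
            if not want_witness:
                return True, None
            node, choices = wit
            choices = dict(choices)
            if rp not in choices:
                kept = branch.parents(rp)
                if len(kept) == 1:
                    choices[rp] = kept[0]
            return True, (node, choices)
    return False, None


def _region_choices(net, comp, B, IR, CR, keep_inside_for_b):
    """Choices inside a collapsed component region consistent with B.

    ``keep_inside_for_b`` mirrors the caseA surgery (a cross reticulation
    whose leaf is in B keeps its inside parents); caseB keeps the opposite
    sides, so the roles flip.
    """
    choices: dict[int, int] = {}
    for r in IR:
        choices[r] = _any_parent(net, r)
    for r in CR:
        lab = leaf_below_reticulation(net, r)
        parents = sorted(net.parents(r))
        ins = [p for p in parents if p in comp.members]
        outs = [p for p in parents if p not in comp.members]
        inside = (lab is not None and lab in B) == keep_inside_for_b
        if inside:
            choices[r] = ins[0] if ins else parents[0]
        else:
            choices[r] = outs[0] if outs else parents[0]
    return choices


def _lift_collapse(net, comp, B, IR, CR, wit, keep_inside_for_b):
    """Lift a child-instance witness back over a caseA/caseB collapse."""
    node, choices = wit
    lifted = _region_choices(net, comp, B, IR, CR, keep_inside_for_b)
    lifted.update(choices)
    # forced survivors: a cross reticulation that kept several parents stays a
    # reticulation in the child and is already in `choices`; one that kept a
    # single parent was re-classified as a tree node there, and its unique
    # remaining parent is exactly what _region_choices picked.
    return node, lifted


def ccp_solve(
    net: PhyloNetwork,
    B,
    trace: list | None = None,
    want_witness: bool = True,
) -> CCPResult:
    """Decide whether ``B`` is a soft cluster of ``net``.

    ``trace``, when a list, collects one event per reduction performed
    (kind, parent instance, child instances) for auditing.

    Returns the answer, the number m of in-component checks executed, the
    effective reticulation number b = log2(m) (0 when m <= 1), and, for a YES
    answer, a witness valid in ``net``.
    """
    B = frozenset(B)
    X = net.X
    if not B:
        raise ValueError("cluster must be nonempty")
    if not B <= X:
        raise ValueError(
            "cluster contains unknown taxa: %s" % sorted(B - X)
        )
    if B == X:
        raise ValueError("cluster must be a proper subset of the taxon set")
    counter = [0]
    ans, wit = _solve(net, B, counter, trace, want_witness)
    m = counter[0]
    b = math.log2(m) if m >= 1 else 0.0
    witness = None
    if ans and want_witness and wit is not None:
        node, choices = wit
        choices = dict(choices)
        for r in net.reticulations:
            choices.setdefault(r, _any_parent(net, r))
        witness = Witness(node=node, choices=choices)
    return CCPResult(answer=ans, m=m, b=b, witness=witness)


def verify_witness(net: PhyloNetwork, B, witness: Witness) -> bool:
    """Check a witness against ``net``: keeping exactly the chosen in-edge at
    every reticulation, the witness node must lie on a root path and the
    labelled leaves reachable from it must equal B."""
    B = frozenset(B)
    g = net.graph
    chosen = nx.DiGraph()
    chosen.add_nodes_from(g.nodes(data=True))
    for v in g:
        preds = sorted(g.predecessors(v))
        if len(preds) >= 2:
            keep = witness.choices.get(v, preds[0])
            if keep not in preds:
                return False
            chosen.add_edge(keep, v)
        elif preds:
            chosen.add_edge(preds[0], v)
    root = net.root
    if witness.node != root and not nx.has_path(chosen, root, witness.node):
        return False
    labels = net.leaf_labels
    below = {witness.node} | nx.descendants(chosen, witness.node)
    return frozenset(labels[v] for v in below if v in labels) == B


def effective_reticulation_number(net: PhyloNetwork, B) -> float:
    """b(N, B) = log2 of the number of in-component checks the solver runs."""
    return ccp_solve(net, B, want_witness=False).b


def max_effective_reticulation_number(
    net: PhyloNetwork, force: bool = False
) -> float:
    """b(N) = max over all clusters B of b(N, B); enumerates the cluster space."""
    from .distances import enumerate_clusters

    return max(
        ccp_solve(net, B, want_witness=False).b
        for B in enumerate_clusters(net.X, force=force)
    )
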
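"""Rooted phylogenetic networks: data model, eNewick I/O and edge surgery.

A rooted phylogenetic network over a taxon set X is an acyclic digraph with a
single in-degree-0 node (the root) whose labelled out-degree-0 nodes are in
bijection with X.  Nodes of in-degree >= 2 are reticulation nodes (hybridization,
introgression, recombination); they have out-degree exactly 1 in a valid
network.  Unlabelled out-degree-0 nodes ("dummy" nodes) and degree-two nodes are
permitted: both arise as intermediate artifacts of the edge surgery performed by
the containment algorithms.

The eNewick dialect read and written here is the usual #Hk tag dialect: each
reticulation node appears once as a defining occurrence carrying its child
subtree, e.g. ``(h)#H1`` or the leaf-body shorthand ``h#H1``, and once per
additional parent as a bare reference ``#H1``.  Branch lengths and internal node
names are parsed and discarded; the algorithms in this package are purely
topological.
"""

from __future__ import annotations

import enum
from typing import Iterable

import networkx as nx
from networkx.algorithms import isomorphism

from .errors import (
    NetworkCycleError,
    NetworkFormatError,
    NetworkValidationError,
)

__all__ = [
    "NodeClass",
    "PhyloNetwork",
    "parse_enewick",
    "write_enewick",
    "read_enewick_file",
]

_LABEL_FORBIDDEN = set("(),;:#")


def descendants_of(g: nx.DiGraph, v: int) -> set[int]:
    """Proper descendants of v by plain stack BFS (hot-path replacement for
    nx.descendants)."""
    succ = g._succ
    seen: set[int] = set()
    stack = [v]
    while stack:
        for w in succ[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    seen.discard(v)
    return seen


def find_root(g: nx.DiGraph) -> int:
    roots = [n for n, p in g._pred.items() if not p]
    if len(roots) != 1:
        raise NetworkValidationError(
            "network must have exactly one root, found %d" % len(roots)
        )
    return roots[0]


class NodeClass(enum.Enum):
    """Classification of a network node by local degrees and labelling."""

    ROOT = "root"
    TREE = "tree"
    RETICULATION = "reticulation"
    LABELED_LEAF = "labeled_leaf"
    DUMMY = "dummy"


class PhyloNetwork:
    """A rooted phylogenetic network backed by a :class:`networkx.DiGraph`.

    Node identifiers are opaque integers that survive edge surgery, so that
    witnesses reported by the containment solver refer to stable nodes.
    Editing operations (:meth:`delete_edges`, :meth:`replace_below`) are
    functional: they return a new network and leave the receiver untouched.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def add_node(self, label: str | None = None) -> int:
        v = self._next_id
        self._next_id += 1
        if label is None:
            self.graph.add_node(v)
        else:
            self.graph.add_node(v, label=label)
        return v

    def add_edge(self, u: int, v: int) -> None:
        if u not in self.graph or v not in self.graph:
            raise KeyError("both endpoints must be existing nodes")
        self.graph.add_edge(u, v)

    def copy(self) -> "PhyloNetwork":
        # hand-rolled copy of the DiGraph internals: the solver copies the
        # graph once per recursion step, and nx.DiGraph.copy dominates there
        g = self.graph
        g2 = nx.DiGraph()
        g2._node = {n: d.copy() for n, d in g._node.items()}
        succ = {n: {} for n in g._node}
        pred = {n: {} for n in g._node}
        for u, nbrs in g._succ.items():
            su = succ[u]
            for v in nbrs:
                d = {}
                su[v] = d
                pred[v][u] = d
        g2._succ = succ
        g2._pred = pred
        other = PhyloNetwork.__new__(PhyloNetwork)
        other.graph = g2
        other._next_id = self._next_id
        return other

    # -- basic queries ----------------------------------------------------

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    @property
    def root(self) -> int:
        return find_root(self.graph)

    def label_of(self, v: int) -> str | None:
        return self.graph.nodes[v].get("label")

    @property
    def leaf_labels(self) -> dict[int, str]:
        return {
            v: d["label"]
            for v, d in self.graph.nodes(data=True)
            if "label" in d
        }

    @property
    def X(self) -> frozenset[str]:
        """The taxon set: labels of the labelled leaves."""
        return frozenset(self.leaf_labels.values())

    def leaf_with_label(self, label: str) -> int:
        for v, lab in self.leaf_labels.items():
            if lab == label:
                return v
        raise KeyError(label)

    def parents(self, v: int) -> list[int]:
        return list(self.graph.predecessors(v))

    def children(self, v: int) -> list[int]:
        return list(self.graph.successors(v))

    def classify(self, v: int) -> NodeClass:
        """Classify ``v`` from its in/out degree and labelling alone."""
        if v not in self.graph:
            raise KeyError("unknown node %r" % (v,))
        if self.graph.in_degree(v) == 0:
            return NodeClass.ROOT
        if self.graph.out_degree(v) == 0:
            if "label" in self.graph.nodes[v]:
                return NodeClass.LABELED_LEAF
            return NodeClass.DUMMY
        if self.graph.in_degree(v) >= 2:
            return NodeClass.RETICULATION
        return NodeClass.TREE

    @property
    def reticulations(self) -> list[int]:
        """Nodes of in-degree >= 2 with a child (R(N))."""
        g = self.graph
        return [v for v, p in g._pred.items() if len(p) >= 2 and g._succ[v]]

    def reticulation_child(self, r: int) -> int:
        kids = self.children(r)
        if len(kids) != 1:
            raise NetworkValidationError(
                "reticulation %r must have exactly one child" % (r,)
            )
        return kids[0]

    def descendants(self, v: int) -> set[int]:
        """All proper descendants of ``v``."""
        return descendants_of(self.graph, v)

    def leaves_below(self, v: int) -> frozenset[str]:
        """Labels of labelled leaves reachable from ``v`` (including v itself)."""
        labels = self.leaf_labels
        out = set()
        if v in labels:
            out.add(labels[v])
        for w in descendants_of(self.graph, v):
            if w in labels:
                out.add(labels[w])
        return frozenset(out)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`NetworkValidationError` on any invariant violation."""
        g = self.graph
        if len(g) == 0:
            raise NetworkValidationError("empty network")
        roots = [v for v in g if g.in_degree(v) == 0]
        if len(roots) != 1:
            raise NetworkValidationError(
                "expected one root, found %d (two roots arise from edge "
                "deletion that disconnects a subnetwork)" % len(roots)
            )
        if not nx.is_directed_acyclic_graph(g):
            raise NetworkCycleError("network contains a directed cycle")
        seen: dict[str, int] = {}
        for v, d in g.nodes(data=True):
            lab = d.get("label")
            if lab is not None:
                if g.out_degree(v) != 0:
                    raise NetworkValidationError(
                        "labelled node %r (%s) must be a leaf" % (v, lab)
                    )
                if lab in seen:
                    raise NetworkValidationError("duplicate leaf label %r" % lab)
                seen[lab] = v
            if g.in_degree(v) >= 2 and g.out_degree(v) > 1:
                raise NetworkValidationError(
                    "reticulation node %r must have out-degree 1" % (v,)
                )

    # -- edge surgery -------------------------------------------------------

    def delete_edges(self, edges: Iterable[tuple[int, int]]) -> "PhyloNetwork":
        """Return the subnetwork N - E: same node set, edges E removed."""
        edges = list(edges)
        for e in edges:
            if not self.graph.has_edge(*e):
                raise ValueError("edge %r not in network" % (e,))
        out = self.copy()
        out.graph.remove_edges_from(edges)
        return out

    def replace_below(self, r: int, label: str) -> "PhyloNetwork":
        """Replace the subnetwork below ``r`` with a single leaf labelled ``label``.

        Descendants of ``r`` that remain reachable from the root through edges
        not passing through ``r`` are kept (only their ancestry through ``r``
        is severed); everything reachable exclusively through ``r`` is removed,
        and a fresh leaf labelled ``label`` becomes the unique child of ``r``.
        """
        if r not in self.graph:
            raise KeyError("unknown node %r" % (r,))
        if label not in self.leaves_below(r):
            raise ValueError("label %r is not below node %r" % (label, r))
        return self._replace_below_any(r, label)

    def _replace_below_any(self, r: int, label: str) -> "PhyloNetwork":
        # Same as replace_below but without requiring `label` to be below r
        # (callers must guarantee the result has unique leaf labels).
        root = r if self.graph.in_degree(r) == 0 else self.root
        out = self.copy()
        g = out.graph
        below = descendants_of(g, r)
        g.remove_edges_from(list(g.out_edges(r)))
        kept = {root} | descendants_of(g, root)
        doomed = below - kept
        g.remove_nodes_from(doomed)
        leaf = out.add_node(label)
        g.add_edge(r, leaf)
        return out

    # -- comparison ---------------------------------------------------------

    def isomorphic_to(self, other: "PhyloNetwork") -> bool:
        """Graph isomorphism respecting leaf labels."""
        nm = isomorphism.categorical_node_match("label", None)
        gm = isomorphism.DiGraphMatcher(self.graph, other.graph, node_match=nm)
        return gm.is_isomorphic()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return "<PhyloNetwork |V|=%d |E|=%d |X|=%d |R|=%d>" % (
            len(self.graph),
            self.graph.number_of_edges(),
            len(self.X),
            len(self.reticulations),
        )


# ---------------------------------------------------------------------------
# eNewick parsing
# ---------------------------------------------------------------------------


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0
        self.net = PhyloNetwork()
        # #H tag -> reticulation node id
        self.hybrid: dict[str, int] = {}
        self.defined: set[str] = set()
        self.referenced: set[str] = set()

    def error(self, msg: str) -> NetworkFormatError:
        return NetworkFormatError("%s (at position %d)" % (msg, self.pos))

    def peek(self) -> str:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self) -> str:
        c = self.peek()
        self.pos += 1
        return c

    def read_name(self) -> tuple[str | None, str | None]:
        """Read an optional ``label#Htag:length`` chunk; length is discarded."""
        start = self.pos
        while self.pos < len(self.text):
            c = self.text[self.pos]
            if c in "(),;:" or c.isspace():
                break
            self.pos += 1
        chunk = self.text[start : self.pos]
        # optional branch length, discarded
        if self.peek() == ":":
            self.take()
            s = self.pos
            while self.pos < len(self.text) and (
                self.text[self.pos].isdigit()
                or self.text[self.pos] in ".eE+-"
            ):
                self.pos += 1
            try:
                float(self.text[s : self.pos])
            except ValueError:
                raise self.error("malformed branch length")
        if not chunk:
            return None, None
        if "#" in chunk:
            label, _, tag = chunk.partition("#")
            if not tag:
                raise self.error("empty #H tag")
            return (label or None), tag
        return chunk, None

    def hybrid_node(self, tag: str) -> int:
        if tag not in self.hybrid:
            self.hybrid[tag] = self.net.add_node()
        return self.hybrid[tag]

    def attach(self, parent: int | None, child: int) -> None:
        if parent is None:
            return
        g = self.net.graph
        if g.has_edge(parent, child):
            # Parallel edge in the written form: realise it through a
            # degree-two pass-through node so in-degrees are preserved.
            mid = self.net.add_node()
            g.add_edge(parent, mid)
            g.add_edge(mid, child)
        else:
            g.add_edge(parent, child)

    def parse_subtree(self, parent: int | None) -> int:
        if self.peek() == "(":
            self.take()
            children_pending: list[tuple[str | None, str | None, int | None]] = []
            kids: list[int] = []
            while True:
                kids.append(self.parse_subtree_placeholder())
                c = self.take()
                if c == ",":
                    continue
                if c == ")":
                    break
                raise self.error("expected ',' or ')'")
            label, tag = self.read_name()
            if tag is not None:
                node = self.hybrid_node(tag)
                if tag in self.defined:
                    raise self.error("duplicate definition of #%s" % tag)
                self.defined.add(tag)
            else:
                node = self.net.add_node()
                # internal labels are discarded (topology only)
            for k in kids:
                self.attach(node, k)
            self.attach(parent, node)
            return node
        # leaf or bare reference
        label, tag = self.read_name()
        if tag is not None:
            node = self.hybrid_node(tag)
            if label is not None:
                # leaf-body definition  label#Htag : reticulation above a leaf
                if tag in self.defined:
                    raise self.error("duplicate definition of #%s" % tag)
                self.defined.add(tag)
                leaf = self.net.add_node(label)
                self.attach(node, leaf)
            else:
                self.referenced.add(tag)
            self.attach(parent, node)
            return node
        node = self.net.add_node(label)  # label may be None: dummy leaf
        self.attach(parent, node)
        return node

    # indirection so kids are created before their parent exists;
    # edges are attached by the caller through `attach`.
    def parse_subtree_placeholder(self) -> int:
        return self.parse_subtree(None)

    def parse(self) -> PhyloNetwork:
        if not self.text.strip():
            raise self.error("empty eNewick string")
        top = self.parse_subtree(None)
        if self.take() != ";":
            raise self.error("expected terminating ';'")
        dangling = (self.referenced | set(self.hybrid)) - self.defined
        if dangling:
            raise NetworkFormatError(
                "dangling #H reference(s): %s" % ", ".join(sorted(dangling))
            )
        if top not in self.net.graph:
            raise self.error("empty network")
        if not nx.is_directed_acyclic_graph(self.net.graph):
            raise NetworkCycleError("#H tag structure induces a cycle")
        self.net.validate()
        return self.net


def parse_enewick(text: str) -> PhyloNetwork:
    """Parse a single ';'-terminated eNewick string into a network.

    Each ``#Hk`` tag must have exactly one defining occurrence (a subtree body
    ``(...)#Hk`` or leaf body ``h#Hk``) and may have any number of bare
    references ``#Hk``; the reticulation node acquires one incoming edge per
    occurrence.
    """
    return _Parser(text).parse()


def read_enewick_file(path) -> list[PhyloNetwork]:
    """Read one network per non-empty line from an eNewick file."""
    nets = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                nets.append(parse_enewick(line))
    return nets


# ---------------------------------------------------------------------------
# eNewick writing
# ---------------------------------------------------------------------------


def write_enewick(net: PhyloNetwork) -> str:
    """Serialize a network to eNewick.

    Deterministic: children are ordered by node identifier and #H tags are
    numbered in DFS discovery order, so identical networks (same ids) always
    serialize identically.  The output re-parses to an isomorphic network.
    """
    g = net.graph
    root = net.root
    tags: dict[int, int] = {}

    def emit(v: int) -> str:
        indeg = g.in_degree(v)
        if indeg >= 2:
            if v in tags:
                return "#H%d" % tags[v]
            tags[v] = len(tags) + 1
            body = _emit_body(v)
            return body + "#H%d" % tags[v]
        return _emit_body(v)

    def _emit_body(v: int) -> str:
        kids = sorted(g.successors(v))
        if not kids:
            lab = net.label_of(v)
            if lab is not None:
                _check_label(lab)
                return lab
            return ""  # dummy node
        return "(" + ",".join(emit(k) for k in kids) + ")"

    return emit(root) + ";"


def _check_label(lab: str) -> None:
    bad = set(lab) & _LABEL_FORBIDDEN
    if bad:
        raise NetworkFormatError(
            "taxon label %r contains forbidden character(s) %s"
            % (lab, sorted(bad))
        )
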
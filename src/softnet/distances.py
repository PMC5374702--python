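"""Cluster enumeration, soft/hard cluster sets, and the SRF and RF distances.

The (hardwired) Robinson-Foulds distance between two rooted networks on the
same taxa is half the size of the symmetric difference of their hard cluster
sets (the taxa below each node).  The *soft* Robinson-Foulds (SRF) distance
replaces hard clusters with soft clusters - the clusters represented by some
node of some displayed tree - and therefore needs one cluster-containment call
per candidate cluster: the whole cluster space 2^|X| - 2 is enumerated and the
CCP solver is asked about each side.  Both distances are pseudometrics; SRF can
vanish between distinct networks that display the same trees.

Half-integer values are possible for networks (the symmetric difference need
not have even cardinality), so distances are reported as exact rationals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterator

import networkx as nx

from .ccp import ccp_solve
from .errors import GuardError, TaxonMismatchError
from .network import PhyloNetwork

__all__ = [
    "Cluster",
    "ClusterSet",
    "DistanceReport",
    "enumerate_clusters",
    "cluster_space_size",
    "soft_cluster_set",
    "hard_cluster_set",
    "srf_distance",
    "rf_distance",
    "parallel_map_clusters",
]

Cluster = frozenset  # a cluster is a proper nonempty frozenset of taxon labels

#: refuse to enumerate the cluster space above this many taxa
TAXA_GUARD = 25


@dataclass(frozen=True)
class ClusterSet:
    """A collection of clusters over a common taxon set."""

    members: frozenset
    origin: str  # "soft" or "hard"
    X: frozenset

    def __contains__(self, B) -> bool:
        return frozenset(B) in self.members

    def __len__(self) -> int:
        return len(self.members)

    @property
    def size_with_trivial(self) -> int:
        return len(self.members)

    @property
    def size_nontrivial(self) -> int:
        return sum(1 for b in self.members if len(b) > 1)


@dataclass(frozen=True)
class DistanceReport:
    """A cluster-based network distance: (left_only + right_only) / 2."""

    value: Fraction
    left_only: int
    right_only: int
    kind: str
    n_clusters_tested: int | None = None

    def __post_init__(self):
        assert self.value == Fraction(self.left_only + self.right_only, 2)

    def __float__(self) -> float:
        return float(self.value)


def cluster_space_size(X) -> int:
    return 2 ** len(X) - 2


def enumerate_clusters(
    X, k: int | None = None, force: bool = False
) -> Iterator[Cluster]:
    """Yield clusters over X: proper nonempty subsets, by ascending size then
    lexicographically; with ``k`` only the size-k ones."""
    labels = sorted(X)
    n = len(labels)
    if n < 2:
        raise ValueError("cluster enumeration needs at least two taxa")
    if n > TAXA_GUARD and not force:
        raise GuardError(
            "%d taxa exceed the cluster-space guard (%d); pass force=True "
            "to override" % (n, TAXA_GUARD)
        )
    sizes = range(1, n) if k is None else [k]
    for size in sizes:
        if not 1 <= size <= n - 1:
            raise ValueError("cluster size must be between 1 and |X|-1")
        for combo in itertools.combinations(labels, size):
            yield frozenset(combo)


def hard_cluster_set(net: PhyloNetwork) -> ClusterSet:
    """The taxa below each node, in one bottom-up pass; proper nonempty sets."""
    g = net.graph
    labels = net.leaf_labels
    X = net.X
    below: dict[int, frozenset] = {}
    members = set()
    for v in reversed(list(nx.topological_sort(g))):
        s = set()
        if v in labels:
            s.add(labels[v])
        for w in g.successors(v):
            s |= below[w]
        below[v] = frozenset(s)
        if s and below[v] != X:
            members.add(below[v])
    return ClusterSet(members=frozenset(members), origin="hard", X=X)


def soft_cluster_set(net: PhyloNetwork, force: bool = False) -> ClusterSet:
    """All soft clusters of the network: one CCP call per candidate cluster.

    Hard clusters are soft, so the solver is only consulted for the rest.
    """
    hard = hard_cluster_set(net).members
    members = set(hard)
    for B in enumerate_clusters(net.X, force=force):
        if B in members:
            continue
        if ccp_solve(net, B, want_witness=False).answer:
            members.add(B)
    return ClusterSet(members=frozenset(members), origin="soft", X=net.X)


def _check_same_taxa(net1: PhyloNetwork, net2: PhyloNetwork) -> None:
    if net1.X != net2.X:
        raise TaxonMismatchError(net1.X - net2.X, net2.X - net1.X)


def rf_distance(net1: PhyloNetwork, net2: PhyloNetwork) -> DistanceReport:
    """Hardwired RF distance: half the symmetric difference of hard clusters."""
    _check_same_taxa(net1, net2)
    c1 = hard_cluster_set(net1).members
    c2 = hard_cluster_set(net2).members
    left, right = len(c1 - c2), len(c2 - c1)
    return DistanceReport(
        value=Fraction(left + right, 2), left_only=left, right_only=right, kind="RF"
    )


def srf_distance(
    net1: PhyloNetwork,
    net2: PhyloNetwork,
    chunks: int = 1,
    shortcut: bool = True,
    force: bool = False,
) -> DistanceReport:
    """SRF distance: half the symmetric difference of the soft cluster sets.

    ``shortcut`` skips CCP calls for clusters that are hard clusters of a
    network (hard implies soft), which can never change the result; disable it
    to force one solver call per (cluster, network) pair.  ``chunks`` splits
    the cluster enumeration into that many contiguous batches (the merged
    result is identical for every chunk count).
    """
    _check_same_taxa(net1, net2)
    hard1 = hard_cluster_set(net1).members if shortcut else frozenset()
    hard2 = hard_cluster_set(net2).members if shortcut else frozenset()

    def worker(B: Cluster) -> tuple[bool, bool]:
        in1 = B in hard1 or ccp_solve(net1, B, want_witness=False).answer
        in2 = B in hard2 or ccp_solve(net2, B, want_witness=False).answer
        return in1, in2

    results = parallel_map_clusters(net1.X, worker, chunks=chunks, force=force)
    left = sum(1 for _, (a, b) in results if a and not b)
    right = sum(1 for _, (a, b) in results if b and not a)
    return DistanceReport(
        value=Fraction(left + right, 2),
        left_only=left,
        right_only=right,
        kind="SRF",
        n_clusters_tested=len(results),
    )


def parallel_map_clusters(
    X,
    worker: Callable[[Cluster], object],
    chunks: int = 1,
    force: bool = False,
) -> list[tuple[Cluster, object]]:
    """Apply ``worker`` to every cluster over X, in ``chunks`` contiguous batches.

    The enumeration stream is partitioned contiguously; empty trailing chunks
    are allowed when chunks exceeds the number of clusters.  The merged result
    list is in enumeration order and identical for every chunk count.
    """
    if chunks < 1:
        raise ValueError("chunks must be >= 1")
    total = cluster_space_size(X)
    per = -(-total // chunks)  # ceil
    stream = enumerate_clusters(X, force=force)
    out: list[tuple[Cluster, object]] = []
    while True:
        batch = list(itertools.islice(stream, per))
        if not batch:
            break
        out.extend((B, worker(B)) for B in batch)
    return out
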
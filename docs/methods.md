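# Methods

## Model and scope

A rooted phylogenetic network over a taxon set X is an acyclic digraph with a
unique in-degree-0 root whose labelled out-degree-0 nodes are in bijection
with X. Nodes of in-degree ≥ 2 are reticulation nodes and must have
out-degree 1 in a valid network; degree-two nodes and unlabelled out-degree-0
("dummy") nodes are permitted because the solver's edge surgery creates them
transiently. Everything is purely topological: branch lengths in input files
are parsed and discarded, and internal node names are dropped.

A tree T is displayed in N when it results from keeping one in-edge per
reticulation, deleting nodes on no root-to-leaf path, and contracting
degree-two nodes. B ⊂ X (proper, nonempty) is a soft cluster when some
displayed tree has a node with leaf set exactly B. For networks carrying
debris (dummies, detached parts), a parent choice that strands part of X
yields a tree over a smaller label set; such trees are not displayed by
definition and the oracle excludes them (they cannot occur in clean inputs,
where every leaf retains a chosen path to the root).

## Decomposition conventions

Components: one per reticulation r (rooted at its child) plus one for the
network root; when c(r) is itself a reticulation the component degenerates to
{c(r)}, and a childless reticulation has an empty component.

Two definitional points were genuinely open and are fixed as follows:

* **Triviality.** A component is trivial when it is empty, or when it carries
  at most one leaf and has no reticulation right below it (a bare chain). The
  degenerate {c(r)} case is always non-trivial. This reading makes the
  machinery self-consistent: every reticulation right below an *exposed*
  component (one with only trivial components right below) then leads to a
  single leaf through a chain of out-degree-1 nodes, which is exactly what the
  L_r / Ľ_r leaf formulas and the in-component check require. It also
  prevents the solver from re-selecting the two-node chain component that
  every collapse leaves behind. With this convention, "contains only one
  leaf" as a separate exposure condition is vacuous (a single-leaf chain has
  nothing right below it), so exposure reduces to "everything right below is
  trivial".
* **Visibility.** For exposed components the exact characterisation is used:
  visible iff the component contains a leaf, or some inner reticulation
  (all parents inside) with a leaf below exists. For arbitrary components the
  package also offers the exact path-based test (node v is visible on leaf ℓ
  iff ℓ is unreachable from the root after removing v), and the two are
  asserted to agree on exposed components in the test suite.

## The solver

Each recursion step tidies the instance (drops nodes that are unreachable or
lead to no leaf — neither can appear in a displayed tree over X), decomposes
it, and selects a non-trivial component whose right-below components are all
trivial, preferring visible components, then smaller ones, with node-id
tie-breaks for reproducibility. Then:

* **Visible component.** One bottom-up pass answers "is B a soft cluster at a
  node of C_r". For each node v, the taxa below v under the admissible parent
  choices split into mandatory(v) (component leaves under v, plus leaves of
  right-below reticulations all of whose parents are under v) and optional(v)
  (leaves of reticulations with parents both under and not under v); success
  at v means mandatory(v) ⊆ B ⊆ mandatory(v) ∪ optional(v). On failure with
  L_r ⊆ B the cross reticulations are retargeted (keep inside parents when
  their leaf is in B, outside otherwise) and the component collapses to the
  leaf ℓ = min(L_r), with B rewritten to (B \ B̂) ∪ {ℓ} where B̂ = L_r ∪ Ľ_r.
  On failure with L_r ∩ B = ∅ the opposite retargeting applies and B is
  unchanged. When L_r straddles B and its complement, failure of the
  in-component check is final for the whole instance.
* **Non-visible component.** Some cross reticulation below it is resolved
  both ways (inside-only / outside-only in-edges); the answer is the
  disjunction. The degenerate {c(r)} component resolves c(r) against its
  parent r in the same way.

The replacement leaf is always min(L_r) (lexicographic), and the split
reticulation the smallest eligible node id; both choices are arbitrary for
correctness and fixed for determinism. The rewrite B′ = (B \ B̂) ∪ {ℓ} re-adds
the replacement leaf after removing B̂ — with ℓ drawn from L_r ⊆ B̂ this is the
only reading under which the collapsed component stays represented in the
reduced cluster, and it is the one validated instance-by-instance against the
oracle. In the L_r ∩ B = ∅ case ℓ = min(L_r) is simultaneously "a leaf below
the component" and "a label outside B", since the original leaf so labelled is
always removed by the collapse. No memoization is performed; every branch is
an independent instance.

**Instrumentation.** m counts executions of the in-component check across the
recursion; b(N, B) = log₂ m (0 when m ≤ 1). A run that short-circuits on a
singleton cluster performs no check, so m = 0 there; a reticulation-free
network costs exactly m = 1. Reported b values therefore measure work in
units of component checks; comparisons against other counting conventions are
qualitative.

**Witnesses.** The in-component check derives explicit parent choices at the
right-below reticulations; every reduction then lifts the child witness one
level: forced or removed reticulations get the parent the surgery kept
(inside/outside roles swap between the two visible-component cases),
reticulations collapsed with the component get a parent consistent with B,
and split-forced reticulations get their surviving parent. The result is a
complete reticulation→parent map for the input network; `verify_witness`
checks it independently (keep the chosen in-edges, confirm the witness node
sits on a root path and its reachable leaf set equals B), and the test suite
enforces this for every YES answer it sees.

## Distances

Hard clusters come from one bottom-up label-set pass; soft clusters from one
CCP call per enumerated cluster, skipping clusters already known hard (hard ⊆
soft, so the shortcut cannot change the result; it can be disabled). Cluster
enumeration is by ascending size, lexicographic within size, and refuses
|X| > 25 without an explicit override (the space doubles per taxon);
displayed-tree enumeration similarly refuses |R| > 20. Distances are exact
rationals (`fractions.Fraction`): the symmetric difference need not have even
cardinality for networks, so half-integers occur. Trivial clusters belong to
both sets and cancel in every distance; set sizes are reported both with and
without them since published counts are ambiguous on this point. Chunked
evaluation partitions the enumeration stream contiguously and is
contract-identical to serial evaluation for every chunk count.

## The generator

`random_network` grows a uniform-attachment rooted binary tree on n leaves
(labels t1..tn), then adds reticulations one at a time by sampling an ordered
pair of distinct edges whose connection preserves acyclicity, subdividing both
and directing a new edge between the subdivision points; rejection with
bounded retries handles constraint failures. Exactly the requested number of
reticulations results, each with in-degree 2; multi-combining mode afterwards
aims extra in-edges (default: half the reticulation count, at least one) at
existing reticulations. Repeated hits can stack reticulations above
reticulations, so the ensemble includes non-reticulation-visible networks and
degenerate reticulation-child components — the hard cases the solver's split
handles — with positive frequency. All randomness flows from one integer
seed; identical specifications serialize byte-identically.

What the generator does **not** emulate: branch lengths, taxon-sampling
biases, any empirical distribution over network shapes, or reconstruction
noise. Passing tests show the algorithms are correct on arbitrary
topologies of the tested sizes, not that the distances behave well on networks
inferred from real data. One ensemble-dependent consequence shows up directly
in the distribution study: the SRF range always dominates the RF range, but
the *shape* of the SRF distribution tracks how reticulate the ensemble is —
with 10 reticulations on only 5 leaves the soft-cluster sets are close to
saturated, so SRF mass piles up near the top of its range (left skew) rather
than near small distances. Distribution-shape comparisons made with a
different random-network generator need not transfer to this one.

## Problem sizes and numerical choices

The validation suites run at sizes where the brute-force oracle is exact and
fast: solver-vs-oracle agreement over the full cluster space on 200 networks
(≤ 8 leaves, ≤ 6 reticulations), SRF agreement on 50 pairs (≤ 7 leaves, ≤ 5
reticulations), reduction soundness on 500 sampled reduction events,
pseudometric checks on 100 triples, a 1000-pair distribution study at
5 leaves/10 reticulations, and an effective-reticulation-number survey on 20
networks at 10 leaves/10 reticulations; `scripts/acceptance.py` re-runs the
same computations at moderately smaller sizes. Distances and cluster
comparisons are exact set arithmetic — there are no tolerances anywhere; the
only floating-point quantity is b = log₂ m, compared against integer bounds.

## Known limitations

* SRF cost is Θ(2^|X|) CCP calls; beyond ~16 taxa the enumeration itself
  dominates. The guards make the cost explicit rather than soft-failing.
* The solver targets correctness and auditability (functional reductions, one
  graph copy per step); an in-place implementation would be faster by a
  constant factor.
* eNewick parallel edges (two in-edges of one reticulation from the same
  parent) are realised through an inserted degree-two node, which preserves
  displayed trees but not the literal multigraph.
* Witness maps fix one parent per reticulation of the whole network even
  though only the choices above B-relevant leaves matter; irrelevant entries
  default to the smallest parent id.
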
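# softnet

Cluster containment and soft Robinson–Foulds distances for rooted phylogenetic
networks.

## The problem

Hybridization, introgression, lateral gene transfer and recombination make the
history of many genome sets reticulate: a rooted **phylogenetic network** — an
acyclic digraph whose labelled leaves are the taxa and whose in-degree ≥ 2
nodes (*reticulation nodes*) model the reticulate events — replaces the
phylogenetic tree. Network models are typically built from, and validated
against, gene trees and clusters, which raises the **cluster containment
problem (CCP)**: given a network *N* over taxa *X* and a cluster
*B* ⊂ *X*, is *B* a **soft cluster** of *N*, i.e. the leaf set below some node
of some tree **displayed** in *N* (keep one in-edge per reticulation, prune
off-path nodes, contract degree-two nodes)? The CCP is NP-complete on
arbitrary networks.

Comparing two reconstructed networks *N₁*, *N₂* on the same taxa uses the
cluster analogue of the Robinson–Foulds metric. With *C(N)* the set of *hard*
clusters (taxa below each node) and *SC(N)* the set of soft clusters:

    d_RF(N₁, N₂)  = |C(N₁) Δ C(N₂)| / 2
    d_SRF(N₁, N₂) = |SC(N₁) Δ SC(N₂)| / 2

The **soft Robinson–Foulds (SRF)** distance needs one CCP answer per candidate
cluster and per network, so the whole cluster space (2^|X| − 2 subsets) is
enumerated. Both are pseudometrics; d_SRF can vanish between distinct
networks that display the same trees.

## The algorithm

`softnet` solves the CCP by the tree-component decomposition: removing the
reticulation nodes splits *N* into tree components *C_r*, one per reticulation
(plus the root's). The solver repeatedly selects a non-trivial component with
only trivial components right below it, and

* if the component is **visible** (it carries a leaf, or some reticulation
  right below it has all parents inside), one linear bottom-up pass decides
  whether *B* is a soft cluster at a node of *C_r*; otherwise the instance
  either resolves outright or *C_r* is collapsed to a single leaf after
  retargeting the cross reticulations below it, giving one strictly smaller
  equivalent instance;
* if it is **not visible**, one cross reticulation is resolved both ways
  (in-edges from inside only / from outside only) and the answer is the
  disjunction of the two sub-instances.

The number *m* of in-component checks performed measures the empirical
hardness of the instance; *b(N, B) = log₂ m* is the **effective reticulation
number**. The naive alternative enumerates all ∏ᵣ indeg(r) displayed trees
(2^|R| for bi-combining networks), so *b(N, B) < |R(N)|* means the
decomposition search space is smaller than the naive one — in random networks
*b* typically stays below |R|/2. A YES answer carries a machine-checkable
witness: a node plus a reticulation→parent map realising *B* in the original
network.

The package also ships the naive displayed-tree oracle (used to validate the
solver exhaustively and available as an alternative backend), the hardwired RF
distance, and a seeded random-network generator (edge-pair hybridization over
a random binary tree) for simulation studies.

## Worked example

The three-taxon network `((a,(h)#H1)x,(#H1,b)y)r;` has one reticulation
(`#H1`, leaf child `h`) whose parents sit in the two root subtrees, so it
displays exactly the two trees `((a,h),b)` and `(a,(h,b))`:

```sh
$ printf '((a,(h)#H1)x,(#H1,b)y)r;\n' > net.enewick
$ softnet ccp --network net.enewick --cluster a,h --report-b --witness
# softnet 0.1.0 cluster=a,h network=net.enewick
contained	yes
m	1
b	0
witness_node	3
keep_parent	2	3
$ echo $?
0
```

`contained yes` says {a, h} is a soft cluster; `m 1` / `b 0` report that a
single in-component check decided it; the witness says: keep the in-edge of
reticulation node 2 coming from node 3 (= the parent of leaf `a`), and {a, h}
is the leaf set below node 3 in the resulting displayed tree. A cluster mixing
the two sides fails (`exit status 1`):

```sh
$ softnet ccp --network net.enewick --cluster a,b
contained	no
```

Distances against the tree `((a,h),b);`:

```sh
$ printf '((a,h),b);\n' > tree.enewick
$ softnet srf net.enewick tree.enewick
# softnet 0.1.0 chunks=1 net1=net.enewick net2=tree.enewick shortcut=True
{"value": 0.5, "left_only": 1, "right_only": 0, "n_clusters_tested": 6}
```

The network's soft clusters {a},{b},{h},{a,h},{b,h} exceed the tree's by
{b,h}, so the SRF distance is 1/2 — half-integers are possible for networks.
Other subcommands: `rf`, `softclusters`, `gen` (seeded random networks),
`displayed` and `oracle-srf` (brute-force backend), `decompose` (component
dump), `b-survey` and `dist-experiment` (the simulation runners).

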
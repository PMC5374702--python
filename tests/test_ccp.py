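"""The decomposition CCP solver: in-component check, reductions, recursion."""

import math

import pytest

from softnet.ccp import (
    ANSWER_YES,
    ccp_solve,
    component_contains,
    effective_reticulation_number,
    reduce_visible_caseA,
    reduce_visible_caseB,
    split_nonvisible,
    verify_witness,
)
from softnet.decomposition import inner_cross, leaves_L, leaves_Lcheck, tree_components
from softnet.distances import enumerate_clusters
from softnet.errors import ContractError
from softnet.generator import GenSpec, random_network
from softnet.network import parse_enewick
from softnet.oracle import naive_ccp


def _root_component(net):
    return tree_components(net)[net.root]


class TestComponentContains:
    def test_h1fix_positive_with_witness_x(self, h1fix):
        net, n = h1fix.net, h1fix.n
        ok, v = component_contains(net, _root_component(net), {"a", "h"})
        assert ok and v == n["x"]

    def test_h1fix_negative(self, h1fix):
        ok, v = component_contains(
            h1fix.net, _root_component(h1fix.net), {"a", "b"}
        )
        assert not ok and v is None

    def test_tree_clusters_and_singletons(self, cherry_tree):
        comp = _root_component(cherry_tree)
        assert component_contains(cherry_tree, comp, {"a", "b"})[0]
        assert component_contains(cherry_tree, comp, {"a"})[0]
        assert not component_contains(cherry_tree, comp, {"a", "c"})[0]

    def test_trivial_component_rejected(self, h1fix):
        comps = tree_components(h1fix.net)
        with pytest.raises(ContractError):
            component_contains(h1fix.net, comps[h1fix.n["H1"]], {"h"})


class TestCaseA:
    def test_guard_requires_L_subset_of_B(self, h1fix):
        net = h1fix.net
        comp = _root_component(net)
        IR, CR = inner_cross(net, comp)
        L_r = leaves_L(net, comp, IR)
        assert L_r == {"a", "b", "h"}  # so B = {a, h} violates L_r <= B
        with pytest.raises(ContractError):
            reduce_visible_caseA(
                net, comp, frozenset({"a", "h"}), IR, CR, L_r, frozenset()
            )

    def test_bhat_equal_b_answers_yes(self, h1fix):
        net = h1fix.net
        comp = _root_component(net)
        IR, CR = inner_cross(net, comp)
        L_r = leaves_L(net, comp, IR)
        res = reduce_visible_caseA(
            net, comp, frozenset(L_r), IR, CR, L_r, frozenset()
        )
        assert res is ANSWER_YES

    @pytest.mark.parametrize("seed", [11, 23, 37])
    def test_reduction_preserves_oracle_answer(self, seed):
        net = random_network(GenSpec(n_leaves=5, n_reticulations=2, seed=seed))
        comps = tree_components(net)
        for comp in comps.values():
            if comp.is_trivial or comp.is_degenerate or not comp.below_all_trivial:
                continue
            IR, CR = inner_cross(net, comp)
            L_r = leaves_L(net, comp, IR)
            if not L_r:
                continue
            for B in enumerate_clusters(net.X):
                if not (L_r < B):
                    continue
                Lc = leaves_Lcheck(net, comp, CR, B)
                res = reduce_visible_caseA(net, comp, B, IR, CR, L_r, Lc)
                if res is ANSWER_YES:
                    assert naive_ccp(net, B)
                else:
                    b2, n2 = res
                    # Theorem: B soft in N iff the component check hits or
                    # (B', N_a') is a yes-instance
                    in_comp = component_contains(net, comp, B)[0]
                    assert naive_ccp(net, B) == (in_comp or naive_ccp(n2, b2))


class TestCaseB:
    def test_collapse_without_cross_reticulations(self):
        # component {a, b} below a reticulation, all leaves outside B
        net = parse_enewick("(((a,b))#H1,(#H1,(c,d)));")
        comps = tree_components(net)
        comp = next(
            c
            for c in comps.values()
            if {net.label_of(v) for v in c.leaf_members} == {"a", "b"}
        )
        out = reduce_visible_caseB(net, comp, frozenset({"c", "d"}), set())
        assert out.X == {"a", "c", "d"}  # collapsed to the leaf min(L_r) = a
        assert naive_ccp(out, {"c", "d"}) == naive_ccp(net, {"c", "d"})

    @pytest.mark.parametrize("seed", [3, 19, 41])
    def test_reduction_preserves_oracle_answer(self, seed):
        net = random_network(GenSpec(n_leaves=6, n_reticulations=3, seed=seed))
        comps = tree_components(net)
        for comp in comps.values():
            if comp.is_trivial or comp.is_degenerate or not comp.below_all_trivial:
                continue
            IR, CR = inner_cross(net, comp)
            L_r = leaves_L(net, comp, IR)
            if not L_r:
                continue
            for B in enumerate_clusters(net.X):
                if L_r & B or component_contains(net, comp, B)[0]:
                    continue
                n2 = reduce_visible_caseB(net, comp, B, CR)
                assert naive_ccp(net, B) == naive_ccp(n2, B)


class TestSplit:
    def test_split_requires_nonvisible(self, h1fix):
        comp = _root_component(h1fix.net)
        with pytest.raises(ContractError):
            split_nonvisible(h1fix.net, comp)

    def test_split_on_nonvisible_component(self, fig1):
        net = fig1.net
        comps = tree_components(net)
        c5 = comps[fig1.n["r5"]]
        n1, n2 = split_nonvisible(net, c5)
        rp = min(
            r
            for r in inner_cross(net, c5)[1]
        )
        # the resolved reticulation drops to in-degree 1 on the inside branch
        assert n1.graph.in_degree(rp) < net.graph.in_degree(rp)
        assert n2.graph.in_degree(rp) < net.graph.in_degree(rp)
        for B in [{"leaf1", "leaf2"}, {"leaf3", "leaf4"}, {"leaf1", "leaf5"}]:
            assert naive_ccp(net, B) == (naive_ccp(n1, B) or naive_ccp(n2, B))

    def test_split_disjunction_on_random_instances(self):
        """Fifty seeded draws with a non-visible selectable component: the
        answer is the disjunction of the two resolved branches, for all
        clusters."""
        found = 0
        for seed in range(400):
            net = random_network(
                GenSpec(
                    n_leaves=3 + seed % 4, n_reticulations=2 + seed % 4, seed=seed
                )
            )
            comps = tree_components(net)
            target = next(
                (
                    c
                    for c in comps.values()
                    if not c.is_trivial
                    and c.below_all_trivial
                    and (
                        c.is_degenerate
                        or not leaves_L(net, c, inner_cross(net, c)[0])
                    )
                ),
                None,
            )
            if target is None:
                continue
            n1, n2 = split_nonvisible(net, target)
            for B in enumerate_clusters(net.X):
                assert naive_ccp(net, B) == (naive_ccp(n1, B) or naive_ccp(n2, B))
            found += 1
            if found == 50:
                break
        assert found == 50


class TestSolver:
    def test_singleton_clusters_are_free(self, h1fix):
        for x in h1fix.net.X:
            res = ccp_solve(h1fix.net, {x})
            assert res.answer and res.m == 0 and res.b == 0.0

    def test_tree_clusters(self, cherry_tree):
        yes = ccp_solve(cherry_tree, {"a", "b"})
        no = ccp_solve(cherry_tree, {"a", "c"})
        assert yes.answer and not no.answer
        assert yes.m == 1 and yes.b == 0.0  # one in-component check suffices
        assert no.m == 1

    def test_unknown_taxon_rejected(self, cherry_tree):
        with pytest.raises(ValueError):
            ccp_solve(cherry_tree, {"z"})
        with pytest.raises(ValueError):
            ccp_solve(cherry_tree, {"a", "b", "c"})  # not a proper subset

    @pytest.mark.parametrize("seed", range(40))
    def test_agreement_with_oracle_and_witnesses(self, seed):
        net = random_network(
            GenSpec(
                n_leaves=3 + seed % 6,
                n_reticulations=seed % 7,
                bi_combining=(seed % 3 != 0),
                seed=seed + 1000,
            )
        )
        for B in enumerate_clusters(net.X):
            res = ccp_solve(net, B)
            assert res.answer == naive_ccp(net, B)
            if res.answer:
                assert verify_witness(net, B, res.witness)

    def test_every_hard_cluster_is_soft(self):
        for seed in range(15):
            net = random_network(
                GenSpec(n_leaves=5, n_reticulations=4, seed=seed)
            )
            for v in net.nodes:
                B = net.leaves_below(v)
                if B and B != net.X:
                    assert ccp_solve(net, B, want_witness=False).answer

    def test_recursion_stays_within_sanity_bound(self):
        for seed in (5, 17, 29):
            net = random_network(GenSpec(n_leaves=5, n_reticulations=6, seed=seed))
            R = len(net.reticulations)
            for B in enumerate_clusters(net.X):
                trace = []
                ccp_solve(net, B, trace=trace, want_witness=False)
                # every reduction spawns at most two children
                n_instances = 1 + sum(len(e["children"]) for e in trace)
                assert n_instances <= 2**R * (R + 1)


class TestEffectiveReticulationNumber:
    def test_tree_has_b_zero(self, cherry_tree):
        assert effective_reticulation_number(cherry_tree, {"a", "b"}) == 0.0

    def test_b_bounded_by_reticulation_count(self):
        net = random_network(GenSpec(n_leaves=6, n_reticulations=6, seed=99))
        R = len(net.reticulations)
        for B in enumerate_clusters(net.X):
            res = ccp_solve(net, B, want_witness=False)
            assert res.b <= R
            assert res.b == (math.log2(res.m) if res.m else 0.0)
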
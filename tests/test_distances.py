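"""Cluster enumeration, soft/hard cluster sets, SRF and RF distances."""

from fractions import Fraction

import pytest

from softnet.distances import (
    cluster_space_size,
    enumerate_clusters,
    hard_cluster_set,
    parallel_map_clusters,
    rf_distance,
    soft_cluster_set,
    srf_distance,
)
from softnet.ccp import ccp_solve
from softnet.errors import GuardError, TaxonMismatchError
from softnet.generator import GenSpec, random_network, random_pair_stream
from softnet.network import parse_enewick
from softnet.oracle import naive_soft_cluster_set, naive_srf


class TestEnumeration:
    @pytest.mark.parametrize(
        "n,count", [(2, 2), (7, 126), (10, 1022)]
    )
    def test_cluster_space_counts(self, n, count):
        X = {"t%d" % i for i in range(n)}
        assert cluster_space_size(X) == count
        assert sum(1 for _ in enumerate_clusters(X)) == count

    def test_grouped_by_size_then_lexicographic(self):
        X = {"a", "b", "c"}
        got = [tuple(sorted(B)) for B in enumerate_clusters(X)]
        assert got == [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c")]

    def test_k_restriction(self):
        X = {"a", "b", "c", "d"}
        assert sum(1 for _ in enumerate_clusters(X, k=2)) == 6

    def test_guard(self):
        X = {"t%d" % i for i in range(26)}
        with pytest.raises(GuardError):
            list(enumerate_clusters(X))


class TestClusterSets:
    def test_h1fix_soft_set(self, h1fix):
        cs = soft_cluster_set(h1fix.net)
        expect = {
            frozenset(s) for s in [{"a"}, {"b"}, {"h"}, {"a", "h"}, {"b", "h"}]
        }
        assert cs.members == expect
        assert cs.size_with_trivial == 5 and cs.size_nontrivial == 2

    def test_tree_soft_equals_hard(self, cherry_tree):
        assert (
            soft_cluster_set(cherry_tree).members
            == hard_cluster_set(cherry_tree).members
        )

    def test_h1fix_hard_set(self, h1fix):
        expect = {
            frozenset(s) for s in [{"a"}, {"b"}, {"h"}, {"a", "h"}, {"b", "h"}]
        }
        assert hard_cluster_set(h1fix.net).members == expect

    @pytest.mark.parametrize("seed", range(12))
    def test_soft_set_matches_oracle_and_contains_hard(self, seed):
        net = random_network(GenSpec(n_leaves=5, n_reticulations=seed % 5, seed=seed))
        soft = soft_cluster_set(net)
        assert soft.members == naive_soft_cluster_set(net)
        hard = hard_cluster_set(net)
        assert hard.members <= soft.members
        assert all(frozenset({x}) in soft.members for x in net.X)
        # every member individually passes the solver
        assert all(
            ccp_solve(net, B, want_witness=False).answer for B in hard.members
        )


class TestDistances:
    def test_identity(self, h1fix):
        assert srf_distance(h1fix.net, h1fix.net).value == 0
        assert rf_distance(h1fix.net, h1fix.net).value == 0

    def test_classic_tree_pair(self):
        t1 = parse_enewick("((a,b),c);")
        t2 = parse_enewick("(a,(b,c));")
        assert srf_distance(t1, t2).value == 1
        assert rf_distance(t1, t2).value == 1

    def test_half_integer_possible(self):
        net = parse_enewick("((a,(h)#H1),(#H1,b));")
        tree = parse_enewick("((a,h),b);")
        d = srf_distance(net, tree)
        assert d.value == Fraction(1, 2)
        assert d.left_only == 1 and d.right_only == 0

    def test_taxon_mismatch_reports_symmetric_difference(self):
        t1 = parse_enewick("((a,b),c);")
        t2 = parse_enewick("((a,b),d);")
        with pytest.raises(TaxonMismatchError) as ei:
            srf_distance(t1, t2)
        assert ei.value.only_left == {"c"} and ei.value.only_right == {"d"}

    def test_srf_zero_for_distinct_networks(self):
        # a cherry and a network with a redundant reticulation above a display
        # the same single tree: SRF vanishes on non-isomorphic inputs
        plain = parse_enewick("(a,b);")
        redundant = parse_enewick("((a)#H1,(#H1),b);")
        assert not plain.isomorphic_to(redundant)
        assert srf_distance(plain, redundant).value == 0

    def test_shortcut_never_changes_result(self):
        for seed in range(6):
            n1 = random_network(GenSpec(n_leaves=5, n_reticulations=3, seed=seed))
            n2 = random_network(GenSpec(n_leaves=5, n_reticulations=3, seed=seed + 50))
            a = srf_distance(n1, n2, shortcut=True)
            b = srf_distance(n1, n2, shortcut=False)
            assert (a.value, a.left_only, a.right_only) == (
                b.value,
                b.left_only,
                b.right_only,
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_srf_matches_oracle(self, seed):
        spec = GenSpec(n_leaves=5, n_reticulations=4)
        (n1, n2), = list(random_pair_stream(spec, 1, seed=seed))
        assert srf_distance(n1, n2).value == naive_srf(n1, n2).value

    def test_rf_against_independent_recomputation(self):
        for seed in range(8):
            n1 = random_network(GenSpec(n_leaves=6, n_reticulations=3, seed=seed))
            n2 = random_network(GenSpec(n_leaves=6, n_reticulations=3, seed=seed + 9))
            # recompute hard clusters by per-node reachability instead of the
            # bottom-up pass
            def brute(net):
                out = set()
                for v in net.nodes:
                    s = net.leaves_below(v)
                    if s and s != net.X:
                        out.add(s)
                return out
            left = brute(n1) - brute(n2)
            right = brute(n2) - brute(n1)
            rep = rf_distance(n1, n2)
            assert rep.value == Fraction(len(left) + len(right), 2)

    def test_symmetry(self):
        n1 = random_network(GenSpec(n_leaves=5, n_reticulations=3, seed=1))
        n2 = random_network(GenSpec(n_leaves=5, n_reticulations=3, seed=2))
        for fn in (srf_distance, rf_distance):
            assert fn(n1, n2).value == fn(n2, n1).value


class TestParallelChunks:
    def test_chunking_partitions_the_stream(self):
        X = {"a", "b", "c", "d", "e"}
        for chunks in (1, 3, 8, 100):
            res = parallel_map_clusters(X, len, chunks=chunks)
            assert len(res) == cluster_space_size(X)
        assert [b for b, _ in parallel_map_clusters(X, len, chunks=4)] == list(
            enumerate_clusters(X)
        )

    def test_distance_identical_across_chunk_counts(self):
        n1 = random_network(GenSpec(n_leaves=5, n_reticulations=4, seed=5))
        n2 = random_network(GenSpec(n_leaves=5, n_reticulations=4, seed=6))
        ref = srf_distance(n1, n2, chunks=1)
        for chunks in (2, 8, 64):
            got = srf_distance(n1, n2, chunks=chunks)
            assert (got.value, got.left_only, got.right_only) == (
                ref.value,
                ref.left_only,
                ref.right_only,
            )
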
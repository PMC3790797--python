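import random

import pytest
from hypothesis import given, settings, strategies as st

from dtlrec.dtl_core import enumerate_reconciliations_bruteforce
from dtlrec.dtl_graph import build_mpr_graph
from dtlrec.examples import three_mpr_example, unique_mpr_example
from dtlrec.median import d_asym, d_sym, max_support_tree, median_over_nprs
from dtlrec.support import EventKey, mpr_supports, npr_supports, reconciliation_keys
from dtlrec.trees_io import subdivide

from conftest import random_instance


def _keysets(n=3, seed=0):
    rng = random.Random(seed)
    pool = [EventKey(f"u{i}", "D", f"b{i}") for i in range(8)]
    return [frozenset(rng.sample(pool, rng.randint(0, 8))) for _ in range(n)]


class TestDistances:
    def test_identity(self):
        (a,) = _keysets(1)
        assert d_asym(a, a) == 0
        assert d_sym(a, a) == 0

    def test_asymmetric_counts_only_missing_from_first(self):
        e = [EventKey(f"u{i}", "D", "b") for i in range(4)]
        r1 = {e[0], e[1], e[2]}
        r2 = {e[0], e[1], e[3]}
        assert d_asym(r1, r2) == 1 and d_asym(r2, r1) == 1
        assert d_sym(r1, r2) == 2

    def test_containment(self):
        e = [EventKey(f"u{i}", "D", "b") for i in range(5)]
        r1, r2 = set(e[:2]), set(e)
        assert d_asym(r1, r2) == 3
        assert d_asym(r2, r1) == 0
        assert d_sym(r1, r2) == 3

    def test_disjoint_sets(self):
        e = [EventKey(f"u{i}", "D", "b") for i in range(5)]
        r1, r2 = set(e[:2]), set(e[2:])
        assert d_sym(r1, r2) == len(r1) + len(r2)

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_symmetric_distance_is_a_metric(self, data):
        pool = [EventKey(f"u{i}", "D", "b") for i in range(6)]
        sets = [
            frozenset(data.draw(st.sets(st.sampled_from(pool)))) for _ in range(3)
        ]
        a, b, c = sets
        assert d_sym(a, b) == d_sym(b, a)
        assert (d_sym(a, b) == 0) == (a == b)
        assert d_sym(a, c) <= d_sym(a, b) + d_sym(b, c)


def _brute_mprs(G, Sp, costs, bound):
    recs = enumerate_reconciliations_bruteforce(G, Sp, costs, bound + 1e-9)
    best = min(r.found_cost for r in recs)
    return {reconciliation_keys(r) for r in recs if abs(r.found_cost - best) < 1e-9}


class TestMaxSupportTree:
    def test_single_mpr_graph_returns_it_for_both_offsets(self):
        S, G, costs = unique_mpr_example()
        g = build_mpr_graph(G, subdivide(S), costs)
        table = mpr_supports(g)
        for offset in (0.0, 0.5):
            R = max_support_tree(g, table, offset)
            assert reconciliation_keys(R) == next(iter(_brute_mprs(G, g.sprime, costs, g.opt_cost)))

    @pytest.mark.parametrize("seed", range(20))
    def test_attains_bruteforce_optimum_for_both_offsets(self, seed):
        _, Sp, G, costs = random_instance(seed)
        g = build_mpr_graph(G, Sp, costs)
        table = mpr_supports(g)
        mprs = _brute_mprs(G, Sp, costs, g.opt_cost)
        for offset in (0.0, 0.5):
            R = max_support_tree(g, table, offset)
            score = sum(table.f(k) - offset for k in reconciliation_keys(R))
            best = max(sum(table.f(k) - offset for k in ks) for ks in mprs)
            assert score == pytest.approx(best, abs=1e-9)
            assert R.cost(costs) == pytest.approx(g.opt_cost)

    @pytest.mark.parametrize("seed", range(20))
    def test_median_criteria_equal_distance_minimizers(self, seed):
        """The max-sum-of-supports tree minimizes the summed asymmetric
        distance; with supports offset by 1/2 it minimizes the symmetric
        one (checked exhaustively over the MPR set)."""
        _, Sp, G, costs = random_instance(seed + 300)
        g = build_mpr_graph(G, Sp, costs)
        table = mpr_supports(g)
        mprs = list(_brute_mprs(G, Sp, costs, g.opt_cost))
        for offset, dist in ((0.0, d_asym), (0.5, d_sym)):
            by_support = max(
                sum(table.f(k) - offset for k in ks) for ks in mprs
            )
            # distance convention: sum_i d(R, R_i)
            best_dist = min(sum(dist(ks, other) for other in mprs) for ks in mprs)
            argmins = [
                ks
                for ks in mprs
                if sum(dist(ks, other) for other in mprs)
                == best_dist
            ]
            assert any(
                sum(table.f(k) - offset for k in ks) == pytest.approx(by_support)
                for ks in argmins
            )
            R = max_support_tree(g, table, offset)
            assert sum(
                dist(reconciliation_keys(R), other) for other in mprs
            ) == best_dist

    def test_asym_prefers_larger_sets_sym_can_reject_them(self):
        """A reconciliation that adds one extra low-support event wins the
        asymmetric criterion but loses the symmetric one."""
        small = frozenset([EventKey("u", "D", "a")])
        big = small | {EventKey("v", "T", "a", "b")}
        freqs = {EventKey("u", "D", "a"): 1.0, EventKey("v", "T", "a", "b"): 0.4}
        asym = {ks: sum(freqs[k] for k in ks) for ks in (small, big)}
        sym = {ks: sum(freqs[k] - 0.5 for k in ks) for ks in (small, big)}
        assert max(asym, key=asym.get) == big
        assert max(sym, key=sym.get) == small

    def test_deterministic_under_ties(self):
        S, G, costs = three_mpr_example()
        g = build_mpr_graph(G, subdivide(S), costs)
        table = mpr_supports(g)
        r1 = max_support_tree(g, table, 0.5)
        r2 = max_support_tree(g, table, 0.5)
        assert reconciliation_keys(r1) == reconciliation_keys(r2)


class TestMedianOverNprs:
    def test_single_graph_equals_max_support_tree(self):
        S, G, costs = three_mpr_example()
        g = build_mpr_graph(G, subdivide(S), costs)
        table = npr_supports([g])
        assert reconciliation_keys(
            median_over_nprs([g], table, "sym")
        ) == reconciliation_keys(max_support_tree(g, table, 0.5))

    def test_identical_graphs_change_nothing(self):
        S, G, costs = three_mpr_example()
        Sp = subdivide(S)
        graphs = [build_mpr_graph(G, Sp, costs) for _ in range(4)]
        table = npr_supports(graphs)
        assert reconciliation_keys(
            median_over_nprs(graphs, table, "asym")
        ) == reconciliation_keys(max_support_tree(graphs[0], table, 0.0))

    @pytest.mark.parametrize("mode,offset", [("asym", 0.0), ("sym", 0.5)])
    def test_equals_argmax_over_per_graph_bruteforce_optima(self, mode, offset):
        from dtlrec.npr_sampling import PerturbationConfig, sample_npr_graphs

        _, Sp, G, costs = random_instance(404)
        graphs = sample_npr_graphs(G, Sp, costs, PerturbationConfig(0.3, 5, 7))
        table = npr_supports(graphs)
        R = median_over_nprs(graphs, table, mode)
        best = max(
            max(
                sum(table.f(k) - offset for k in ks)
                for ks in _brute_mprs(G, Sp, g.costs, g.opt_cost)
            )
            for g in graphs
        )
        assert R.support_score == pytest.approx(best, abs=1e-9)

    def test_empty_graph_set_rejected(self):
        with pytest.raises(ValueError):
            median_over_nprs([], None, "sym")
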
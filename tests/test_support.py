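import pytest
from hypothesis import given, settings, strategies as st

from dtlrec.dtl_core import enumerate_reconciliations_bruteforce
from dtlrec.dtl_graph import build_mpr_graph
from dtlrec.examples import three_mpr_example, two_mpr_example, unique_mpr_example
from dtlrec.support import (
    EventKey,
    SupportTable,
    event_key,
    filter_events,
    mpr_supports,
    npr_supports,
    reconciliation_keys,
)
from dtlrec.trees_io import subdivide

from conftest import random_instance


class TestEventKey:
    def test_equivalence_is_invariant_under_slice_placement(self):
        """The same D in different slices of one S branch (connected by NE
        chains) projects to one key; brute-force duplicates collapse."""
        _, Sp, G, costs = random_instance(17)
        opt = build_mpr_graph(G, Sp, costs).opt_cost
        recs = enumerate_reconciliations_bruteforce(G, Sp, costs, opt + 1e-9)
        # raw S'-level reconciliations outnumber their S-projections
        raw = {tuple(map(id, r.events)) for r in recs}
        proj = {reconciliation_keys(r) for r in recs}
        assert len(proj) <= len(raw)
        for r in recs:
            for e in r.events:
                if e.etype in ("S", "D", "T", "TL", "SL"):
                    k = event_key(e, G, Sp)
                    assert k.where in Sp.S.ids

    def test_transfers_with_different_receivers_have_different_keys(self):
        S, G, costs = two_mpr_example()
        Sp = subdivide(S)
        from dtlrec.dtl_core import Event

        a = Sp.label_index["A"]
        b = Sp.label_index["B"]
        c = Sp.label_index["C"]
        k1 = event_key(Event(6, "T", c, receiver=a), G, Sp)
        k2 = event_key(Event(6, "T", c, receiver=b), G, Sp)
        assert k1 != k2
        assert k1 == event_key(Event(6, "T", c, receiver=a), G, Sp)


class TestMprSupports:
    def test_unique_mpr_gives_full_support(self):
        S, G, costs = unique_mpr_example()
        g = build_mpr_graph(G, subdivide(S), costs)
        table = mpr_supports(g)
        assert table.freqs and all(f == 1.0 for f in table.freqs.values())

    def test_two_mpr_root_events_have_half_support(self):
        S, G, costs = two_mpr_example()
        g = build_mpr_graph(G, subdivide(S), costs)
        table = mpr_supports(g)
        gid = G.ids[G.root]
        halves = {
            k.etype for k, f in table.freqs.items() if k.gene == gid and f == 0.5
        }
        assert {"S", "D"} <= halves

    def test_no_contemporary_or_noevent_keys(self):
        S, G, costs = two_mpr_example()
        table = mpr_supports(build_mpr_graph(G, subdivide(S), costs))
        assert all(k.etype not in ("C", "NE") for k in table.freqs)

    def test_high_support_events_not_jointly_realizable(self):
        # the headline counter-example: events above 50% support spread
        # over the three MPRs such that no single MPR holds them all
        S, G, costs = three_mpr_example()
        Sp = subdivide(S)
        g = build_mpr_graph(G, Sp, costs)
        table = mpr_supports(g)
        high = {k for k, f in table.freqs.items() if f > 0.5}
        assert high
        recs = enumerate_reconciliations_bruteforce(G, Sp, costs, g.opt_cost + 1e-9)
        best = min(r.found_cost for r in recs)
        mprs = {reconciliation_keys(r) for r in recs if abs(r.found_cost - best) < 1e-9}
        assert not any(high <= ks for ks in mprs)

    @pytest.mark.parametrize("seed", range(15))
    def test_supports_equal_bruteforce_frequencies(self, seed):
        _, Sp, G, costs = random_instance(seed)
        g = build_mpr_graph(G, Sp, costs)
        table = mpr_supports(g)
        recs = enumerate_reconciliations_bruteforce(G, Sp, costs, g.opt_cost + 1e-9)
        best = min(r.found_cost for r in recs)
        mprs = {reconciliation_keys(r) for r in recs if abs(r.found_cost - best) < 1e-9}
        for k in {k for ks in mprs for k in ks} | set(table.freqs):
            assert table.f(k) == pytest.approx(
                sum(1 for ks in mprs if k in ks) / len(mprs)
            )


class TestNprSupports:
    def test_single_graph_reduces_to_mpr_supports(self):
        S, G, costs = two_mpr_example()
        g = build_mpr_graph(G, subdivide(S), costs)
        assert npr_supports([g]).freqs == mpr_supports(g).freqs

    def test_replicated_identical_graphs_change_nothing(self):
        S, G, costs = three_mpr_example()
        Sp = subdivide(S)
        graphs = [build_mpr_graph(G, Sp, costs) for _ in range(5)]
        assert npr_supports(graphs).freqs == mpr_supports(graphs[0]).freqs

    def test_pooling_matches_direct_tally_over_both_mpr_sets(self):
        """f(e) = (count_1 + count_2) / (N_1 + N_2), verified against a
        brute-force tally of both graphs' MPR sets."""
        from dtlrec.dtl_core import CostVector

        S, G, costs = two_mpr_example()
        Sp = subdivide(S)
        costs2 = CostVector(0.4, 2.0, 0.3)  # different optimum structure
        g1 = build_mpr_graph(G, Sp, costs)
        g2 = build_mpr_graph(G, Sp, costs2)
        pooled = npr_supports([g1, g2])

        def mpr_sets(cv, bound):
            recs = enumerate_reconciliations_bruteforce(G, Sp, cv, bound + 1e-9)
            best = min(r.found_cost for r in recs)
            return {
                reconciliation_keys(r)
                for r in recs
                if abs(r.found_cost - best) < 1e-9
            }

        sets1 = mpr_sets(costs, g1.opt_cost)
        sets2 = mpr_sets(costs2, g2.opt_cost)
        total = len(sets1) + len(sets2)
        allkeys = {k for ks in sets1 | sets2 for k in ks}
        assert set(pooled.freqs) == allkeys
        for k in allkeys:
            tally = sum(1 for ks in sets1 if k in ks) + sum(
                1 for ks in sets2 if k in ks
            )
            assert pooled.f(k) == pytest.approx(tally / total)

    def test_empty_graph_list_rejected(self):
        with pytest.raises(ValueError):
            npr_supports([])


class TestFiltering:
    def _table(self):
        return SupportTable(
            {
                EventKey("u", "D", "A"): 1.0,
                EventKey("v", "T", "A", "B"): 0.6,
                EventKey("w", "SL", "N1", "A"): 0.2,
            }
        )

    def test_zero_threshold_is_identity(self):
        t = self._table()
        keys = set(t.freqs) | {EventKey("z", "D", "B")}  # one unsupported event
        assert filter_events(keys, t, 0.0) == keys

    def test_threshold_is_not_smaller_than(self):
        t = self._table()
        assert filter_events(set(t.freqs), t, 0.6) == {
            EventKey("u", "D", "A"),
            EventKey("v", "T", "A", "B"),
        }

    def test_threshold_one_keeps_events_in_every_mpr(self):
        S, G, costs = two_mpr_example()
        g = build_mpr_graph(G, subdivide(S), costs)
        table = mpr_supports(g)
        kept = filter_events(set(table.freqs), table, 1.0)
        Sp = g.sprime
        recs = enumerate_reconciliations_bruteforce(G, Sp, costs, g.opt_cost + 1e-9)
        best = min(r.found_cost for r in recs)
        mprs = [reconciliation_keys(r) for r in recs if abs(r.found_cost - best) < 1e-9]
        inter = frozenset.intersection(*mprs)
        assert kept == set(inter)

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_events(set(), self._table(), 1.5)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.data())
    def test_filtering_is_monotone(self, freqs, data):
        keys = [EventKey(f"u{i}", "D", "A") for i in range(len(freqs))]
        table = SupportTable(dict(zip(keys, freqs)))
        t1 = data.draw(st.floats(0, 1))
        t2 = data.draw(st.floats(0, 1))
        lo, hi = min(t1, t2), max(t1, t2)
        assert filter_events(keys, table, hi) <= filter_events(keys, table, lo)
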
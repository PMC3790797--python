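import math
import random
import statistics

import pytest

from dtlrec.dtl_core import CostVector, reconciliation_cost
from dtlrec.simulate import (
    RateSet,
    costs_from_event_counts,
    derive_costs,
    draw_rates,
    perturb_gene_tree,
    random_dated_species_tree,
    rf_distance,
    simulate_history,
)
from dtlrec.trees_io import subdivide


class TestRates:
    def test_sampling_scheme_intervals(self):
        rng = random.Random(3)
        for _ in range(10_000):
            r = draw_rates(rng)
            assert 0.001 <= r.loss <= 0.0018
            assert 0.5 <= r.birth / r.loss <= 1.1
            assert 0.7 <= r.dup / r.birth <= 1.0
            assert r.transfer >= 0

    def test_bound_arithmetic(self):
        # ratios at their lower bounds: transfer = 0.3 * 0.5 * loss
        loss = 0.001
        birth = loss * 0.5
        dup = birth * 0.7
        r = RateSet(loss=loss, dup=dup, transfer=birth - dup)
        assert r.transfer == pytest.approx(0.3 * 0.5 * loss)

    def test_pure_duplication_share_means_no_transfers(self):
        r = RateSet(loss=0.001, dup=0.0008, transfer=0.0)
        assert r.birth == pytest.approx(0.0008)


class TestSimulateHistory:
    def _tree(self, n=8, h=1000.0, seed=0):
        return random_dated_species_tree(n, h, random.Random(seed))

    def test_zero_rates_give_congruent_history(self):
        S = self._tree()
        h = simulate_history(S, RateSet(0.0, 0.0, 0.0), random.Random(1))
        assert h.counts == {"D": 0, "T": 0, "L": 0}
        assert h.gene_tree.n_leaves == S.n_leaves
        assert all(k.etype == "S" for k in h.true_events)

    def test_true_events_form_a_valid_reconciliation(self):
        S = self._tree()
        Sp = subdivide(S)
        rng = random.Random(5)
        for _ in range(25):
            h = simulate_history(S, draw_rates(rng), rng)
            R = h.to_reconciliation(Sp)
            reconciliation_cost(R, CostVector(1, 1, 1))  # validates
            d, t, l = R.dtl_counts()
            assert (d, t, l) == (h.counts["D"], h.counts["T"], h.counts["L"])

    def test_no_transfer_rate_no_transfer_events(self):
        S = self._tree()
        rng = random.Random(9)
        for _ in range(20):
            h = simulate_history(S, RateSet(0.0015, 0.001, 0.0), rng)
            assert all(k.etype not in ("T", "TL") for k in h.true_events)

    def test_event_counts_scale_with_rates(self):
        S = self._tree()
        rng = random.Random(11)

        def mean_events(scale):
            rs = RateSet(0.0012 * scale, 0.0008 * scale, 0.0002 * scale)
            return statistics.fmean(
                simulate_history(S, rs, rng).n_dtl_events for _ in range(150)
            )

        assert mean_events(3.0) > 1.8 * mean_events(1.0)

    def test_high_loss_rate_triggers_bounded_retry_error(self):
        S = self._tree(n=4, h=2000.0)
        with pytest.raises(RuntimeError, match="degenerate"):
            simulate_history(
                S, RateSet(loss=0.1, dup=0.0, transfer=0.0),
                random.Random(3), max_retries=20,
            )

    def test_study_scale_event_counts(self):
        # 37 species at the drawn rates: order of magnitude of a dozen
        # D/T/L events per family (band, not an equality)
        rng = random.Random(2)
        S = random_dated_species_tree(37, 300.0, rng)
        mean = statistics.fmean(
            simulate_history(S, draw_rates(rng), rng).n_dtl_events
            for _ in range(500)
        )
        assert 5.0 <= mean <= 30.0


class TestDeriveCosts:
    def test_printed_cost_triple_from_frequencies(self):
        # frequencies (0.25, 5/28, 16/28) -> (0.60206, 0.74819, 0.24304)
        cv = costs_from_event_counts(7, 5, 16)
        assert cv.dup == pytest.approx(0.60206, abs=1e-4)
        assert cv.transfer == pytest.approx(0.74819, abs=1e-4)
        assert cv.loss == pytest.approx(0.24303, abs=1e-4)

    def test_equal_counts_give_log10_three(self):
        cv = costs_from_event_counts(4, 4, 4)
        for c in (cv.dup, cv.transfer, cv.loss):
            assert c == pytest.approx(math.log10(3))

    def test_frequencies_recoverable_from_costs(self):
        cv = costs_from_event_counts(10, 3, 7)
        total = 20
        assert 10 ** -cv.dup == pytest.approx(10 / total)
        assert 10 ** -cv.transfer == pytest.approx(3 / total)
        assert 10 ** -cv.loss == pytest.approx(7 / total)

    def test_zero_count_pseudocount_keeps_costs_finite(self):
        cv = costs_from_event_counts(5, 0, 5)
        assert math.isfinite(cv.transfer) and cv.transfer > 0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            costs_from_event_counts(0, 0, 0)

    def test_derive_from_history(self):
        S = random_dated_species_tree(10, 1500.0, random.Random(0))
        rng = random.Random(8)
        h = simulate_history(S, draw_rates(rng), rng)
        if h.n_dtl_events:
            cv = derive_costs(h)
            assert cv.dup > 0 and cv.transfer > 0 and cv.loss > 0


class TestPerturbGeneTree:
    def _gene(self, n=20, seed=0):
        rng = random.Random(seed)
        S = random_dated_species_tree(6, 10.0, rng)
        from conftest import random_gene_tree

        return random_gene_tree(rng, n, sorted(S.leaf_index))

    def test_zero_moves_is_identity(self):
        G = self._gene()
        G2 = perturb_gene_tree(G, n_moves=0, rng=random.Random(0))
        assert rf_distance(G, G2) == 0.0

    def test_one_nni_on_four_leaves_has_maximal_rf(self):
        # all 4-leaf unrooted topologies are one NNI apart: RF jumps to 1
        G = self._gene(n=4, seed=1)
        for seed in range(10):
            G2 = perturb_gene_tree(G, n_moves=1, rng=random.Random(seed))
            assert rf_distance(G, G2) in (0.0, 1.0)
        hits = [
            rf_distance(G, perturb_gene_tree(G, n_moves=1, rng=random.Random(s)))
            for s in range(20)
        ]
        assert 1.0 in hits

    def test_target_rf_band_on_larger_trees(self):
        target = 0.177
        ok = 0
        for seed in range(30):
            G = self._gene(n=25, seed=seed)
            G2 = perturb_gene_tree(G, target_rf=target, rng=random.Random(seed))
            if abs(rf_distance(G, G2) - target) <= 0.05:
                ok += 1
        assert ok >= 27  # >= 90% of trials in the +-0.05 band

    def test_leaf_labels_and_mapping_preserved(self):
        G = self._gene()
        G2 = perturb_gene_tree(G, target_rf=0.3, rng=random.Random(4))
        assert G2.s == G.s
        assert sorted(l for l in G2.labels if l) == sorted(l for l in G.labels if l)

    def test_rf_distance_cross_checked_with_dendropy(self):
        import dendropy

        G = self._gene(n=12, seed=3)
        G2 = perturb_gene_tree(G, n_moves=4, rng=random.Random(5))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=G.newick(), schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=G2.newick(), schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf_distance(G, G2, normalize=False) == expected
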
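"""z-score statistic, triplicate t-test, threshold calls, box/notch statistics
and mark integration."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from oncohistone_screen.differential_epigenome import (
    BoxStats,
    ExpressionRecord,
    box_stats,
    call_differential,
    chip_zscores,
    expression_pairs,
    integrate_marks,
    overlap_sets,
    promoter_set_shift,
    ttest_two_sample,
    zscore,
)
from oncohistone_screen.io_formats import ValidationError
from oncohistone_screen.synthetic_data import SimulationConfig, simulate_expression


class TestZscore:
    def test_rna_mode_arithmetic(self):
        assert zscore(4, 1, absolute_denominator=False) == pytest.approx(3 / math.sqrt(5))

    def test_equal_means_give_zero(self):
        assert zscore(7.3, 7.3, absolute_denominator=True) == 0.0

    def test_absolute_mode_with_negative_net_signal(self):
        assert zscore(-1, 1, absolute_denominator=True) == pytest.approx(-2 / math.sqrt(2))

    def test_zero_denominator_maps_to_zero(self):
        assert zscore(0.0, 0.0, absolute_denominator=False) == 0.0

    def test_rna_mode_rejects_negative_input(self):
        with pytest.raises(ValueError):
            zscore(-1, 1, absolute_denominator=False)

    @given(m=st.floats(-100, 100), w=st.floats(-100, 100))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, m, w):
        assert zscore(m, w, True) == pytest.approx(-zscore(w, m, True), abs=1e-9)

    @given(m=st.floats(0, 100), w=st.floats(0, 100), k=st.floats(0.01, 50))
    @settings(max_examples=200, deadline=None)
    def test_scale_covariance(self, m, w, k):
        """z(kM, kW) = sqrt(k) * z(M, W): the statistic grows with signal
        magnitude, not only with relative change."""
        assert zscore(k * m, k * w, False) == pytest.approx(
            math.sqrt(k) * zscore(m, w, False), rel=1e-6, abs=1e-9
        )


class TestTtest:
    def test_identical_groups(self):
        res = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_example(self):
        res = ttest_two_sample([1, 2, 3], [4, 5, 6])
        assert abs(res.statistic) == pytest.approx(3 / math.sqrt(2 / 3), rel=1e-9)
        assert res.p_value == pytest.approx(0.021312, abs=5e-5)

    def test_zero_variance_unequal_means_gives_p_zero(self):
        assert ttest_two_sample([1, 1], [2, 2]).p_value == 0.0

    def test_zero_variance_equal_means_gives_p_one(self):
        assert ttest_two_sample([2, 2], [2, 2]).p_value == 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            ttest_two_sample([1], [2, 3])

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_scipy_student_t(self, a, b):
        res = ttest_two_sample(a, b)
        ref = scipy.stats.ttest_ind(a, b, equal_var=True)
        if math.isfinite(res.statistic) and not math.isnan(ref.statistic):
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)


def pair(gene, mut, wt):
    return (ExpressionRecord(gene, "MUT", mut), ExpressionRecord(gene, "WT", wt))


class TestCallDifferential:
    def test_threshold_logic(self):
        # strong planted up gene: z >> 1.5, tiny p
        results = call_differential([pair("g1", [80, 81, 79], [20, 21, 19])])
        assert results[0].call == "up"

    def test_z_threshold_is_strict(self):
        # construct means with z exactly 1.5: M - W = 1.5*sqrt(M+W)
        w = 10.0
        m = 17.9268845  # solves (m-w) = 1.5*sqrt(m+w) to ~1e-8
        z = zscore(m, w, False)
        assert z == pytest.approx(1.5, abs=1e-6)
        results = call_differential(
            [pair("g1", [m, m, m], [w, w, w])], z_thresh=z  # exactly at threshold
        )
        assert results[0].call == "ns"

    def test_down_call_symmetric(self):
        results = call_differential([pair("g1", [20, 21, 19], [80, 81, 79])])
        assert results[0].call == "down"

    def test_mismatched_gene_pair_rejected(self):
        with pytest.raises(ValidationError):
            call_differential([(ExpressionRecord("g1", "MUT", [1, 2, 3]),
                                ExpressionRecord("g2", "WT", [1, 2, 3]))])

    def test_recovery_on_planted_simulation(self):
        """expr_effect=4, cv=0.1: nearly all planted up genes called, few false
        discoveries."""
        tp = fn = fp = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, expr_effect=4.0, expr_cv=0.1)
            sim = simulate_expression(cfg)
            up = set(sim.truth.loc[sim.truth.planted == "up", "gene_id"])
            calls = call_differential(expression_pairs(sim.table, "MUT", "WT"))
            called = {r.gene_id for r in calls if r.call == "up"}
            tp += len(called & up)
            fn += len(up - called)
            fp += len(called - up)
        assert tp / (tp + fn) >= 0.9
        assert fp / max(1, tp + fp) <= 0.1

    def test_null_calibration(self):
        """Under the null (no planted effect) with z_thresh=0 the called
        fraction tracks the nominal p threshold."""
        called = total = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, expr_effect=1.0)
            sim = simulate_expression(cfg)
            calls = call_differential(expression_pairs(sim.table, "MUT", "WT"),
                                      z_thresh=0.0, p_thresh=0.05)
            called += sum(1 for r in calls if r.call != "ns")
            total += len(calls)
        rate = called / total
        bound = 1.96 * math.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + bound


class TestOverlap:
    def up(self, genes):
        return [
            type("R", (), {"gene_id": g, "call": "up"})() for g in genes
        ]

    def test_partition(self):
        only_a, shared, only_b = overlap_sets(self.up(["g1", "g2"]), self.up(["g2", "g3"]))
        assert (only_a, shared, only_b) == ({"g1"}, {"g2"}, {"g3"})

    def test_identity(self):
        only_a, shared, only_b = overlap_sets(self.up(["g1"]), self.up(["g1"]))
        assert not only_a and not only_b and shared == {"g1"}

    def test_disjoint(self):
        _, shared, _ = overlap_sets(self.up(["g1"]), self.up(["g2"]))
        assert not shared


def box_oracle(values):
    """Independent Tukey box statistics via the closed-form hinge position
    h = (floor((n+1)/2) + 1) / 2 on the sorted data."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    med = float(np.median(x))
    h = (math.floor((n + 1) / 2) + 1) / 2  # 1-based fractional position
    lo = (x[math.floor(h) - 1] + x[math.ceil(h) - 1]) / 2
    hi_pos = n + 1 - h
    hi = (x[math.floor(hi_pos) - 1] + x[math.ceil(hi_pos) - 1]) / 2
    iqr = hi - lo
    inside = x[(x >= lo - 1.5 * iqr) & (x <= hi + 1.5 * iqr)]
    notch = 1.58 * iqr / math.sqrt(n)
    return BoxStats(n=n, median=med, hinge_lo=float(lo), hinge_hi=float(hi), iqr=float(iqr),
                    whisker_lo=float(inside[0]), whisker_hi=float(inside[-1]),
                    notch_lo=med - notch, notch_hi=med + notch)


class TestBoxStats:
    def test_hand_computed_one_to_nine(self):
        s = box_stats(range(1, 10))
        assert s.median == 5 and (s.hinge_lo, s.hinge_hi) == (3, 7) and s.iqr == 4
        assert s.notch_lo == pytest.approx(5 - 1.58 * 4 / 3)
        assert s.notch_hi == pytest.approx(5 + 1.58 * 4 / 3)

    def test_constant_data(self):
        s = box_stats([4.0] * 6)
        assert s.median == s.hinge_lo == s.hinge_hi == s.whisker_lo == s.whisker_hi == 4.0
        assert s.iqr == 0.0

    def test_single_value(self):
        s = box_stats([2.5])
        assert s.median == s.hinge_lo == s.whisker_hi == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            box_stats([])

    def test_matches_independent_implementation_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            values = rng.normal(size=n) * rng.uniform(0.1, 20)
            got = box_stats(values)
            want = box_oracle(values)
            for f in ("median", "hinge_lo", "hinge_hi", "iqr",
                      "whisker_lo", "whisker_hi", "notch_lo", "notch_hi"):
                assert getattr(got, f) == pytest.approx(getattr(want, f), abs=1e-12), f

    def test_ordering_invariants(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.normal(size=int(rng.integers(1, 40)))
            s = box_stats(v)
            assert s.hinge_lo <= s.median <= s.hinge_hi
            assert v.min() <= s.whisker_lo <= s.whisker_hi <= v.max()


class TestPromoterShift:
    def test_subset_below_notch_flag(self):
        z = {f"g{i}": 0.0 for i in range(50)}
        z.update({f"s{i}": -5.0 for i in range(10)})
        shift = promoter_set_shift(z, {f"s{i}" for i in range(10)})
        assert shift.subset_below_global_notch
        assert shift.subset_stats.median < shift.global_stats.median

    def test_full_set_gives_identical_stats(self):
        z = {f"g{i}": float(i) for i in range(20)}
        shift = promoter_set_shift(z, set(z))
        assert shift.global_stats == shift.subset_stats
        assert not shift.subset_below_global_notch

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            promoter_set_shift({"g": 1.0}, set())

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValidationError):
            promoter_set_shift({"g": 1.0}, {"missing"})


class TestIntegrateMarks:
    def test_sign_patterns(self):
        me3 = {"g": -2.0}
        ac = {"g": 1.5}
        rna = {"g": 2.0}
        assert integrate_marks(me3, ac, rna)["g"] == "derepressed_activated"

    def test_all_zero_is_unchanged(self):
        assert integrate_marks({"g": 0.0}, {"g": 0.0}, {"g": 0.0})["g"] == "unchanged"

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(300)]
        me3 = {g: float(v) for g, v in zip(genes, rng.normal(size=300))}
        ac = {g: float(v) for g, v in zip(genes, rng.normal(size=300))}
        rna = {g: float(v) for g, v in zip(genes, rng.normal(size=300))}
        cats = integrate_marks(me3, ac, rna, eps=0.5)
        assert set(cats) == set(genes)
        assert set(cats.values()) <= {
            "derepressed_activated", "me3_loss_only", "ac_gain_only", "unchanged", "other",
        }

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValidationError):
            integrate_marks({"g": 0.0}, {"h": 0.0}, {"g": 0.0})


class TestChipZscores:
    def test_per_gene_z_from_net_signals(self):
        z = chip_zscores({"g": 1.0}, {"g": 4.0})
        assert z["g"] == pytest.approx(-3 / math.sqrt(5))

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValidationError):
            chip_zscores({"g": 1.0}, {"h": 1.0})
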
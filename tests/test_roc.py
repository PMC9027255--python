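"""ROC construction, AUC identities, DeLong inference, cutoff selection
and the 2x2 metric arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seropanel.roc import (
    ConfusionCounts,
    MarkerCutoff,
    auc_ci_delong,
    bootstrap_auc_se,
    compare_auc_paired,
    confusion_at_cutoff,
    empirical_roc,
    mann_whitney_auc,
    metrics_from_confusion,
    optimal_cutoff,
    reconstruct_confusion,
)


def brute_force_auc(cases, controls):
    """O(n^2) pairwise count with ties scored one half."""
    cases, controls = np.asarray(cases), np.asarray(controls)
    total = 0.0
    for x in cases:
        for y in controls:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(cases) * len(controls))


values_strategy = st.lists(
    st.integers(0, 8).map(float), min_size=1, max_size=25)  # integer grid forces ties


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        curve = empirical_roc([2.0, 3.0], [0.0, 1.0])
        assert curve.auc == pytest.approx(1.0)

    def test_identical_multisets(self):
        curve = empirical_roc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert curve.auc == pytest.approx(0.5)

    def test_curve_anchors_and_monotonicity(self, rng):
        curve = empirical_roc(rng.normal(1, 1, 30), rng.normal(0, 1, 40))
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([], [1.0])

    def test_trapezoid_equals_pairwise_count_fixed(self, rng):
        x = rng.integers(0, 10, 30).astype(float)
        y = rng.integers(0, 10, 30).astype(float)
        curve = empirical_roc(x, y)
        assert curve.auc == pytest.approx(brute_force_auc(x, y), rel=1e-12, abs=1e-12)
        assert mann_whitney_auc(x, y) == pytest.approx(curve.auc, rel=1e-12, abs=1e-12)

    @given(values_strategy, values_strategy)
    @settings(max_examples=60, deadline=None)
    def test_trapezoid_equals_pairwise_count_property(self, x, y):
        curve = empirical_roc(x, y)
        assert curve.auc == pytest.approx(brute_force_auc(x, y), rel=1e-12, abs=1e-12)

    @given(values_strategy, values_strategy)
    @settings(max_examples=40, deadline=None)
    def test_label_flip_duality(self, x, y):
        assert empirical_roc(x, y).auc == pytest.approx(
            1.0 - empirical_roc(y, x).auc, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.lognormal(0, 1, 25)
        y = rng.lognormal(0.5, 1, 25)
        base = empirical_roc(x, y).auc
        for f in (np.log, np.sqrt, lambda v: 3 * v + 7, lambda v: v**3):
            assert empirical_roc(f(x), f(y)).auc == pytest.approx(base, abs=1e-12)


class TestDelong:
    def test_perfect_separation_boundary(self):
        res = auc_ci_delong([10.0, 11.0, 12.0], [0.0, 1.0, 2.0])
        assert res.auc == 1.0 and res.ci == (1.0, 1.0) and res.boundary

    def test_variance_close_to_bootstrap(self, rng):
        x = rng.normal(1.2, 1, 30)
        y = rng.normal(0, 1, 30)
        res = auc_ci_delong(x, y)
        boot = bootstrap_auc_se(x, y, n_boot=10_000, seed=1)
        assert res.se == pytest.approx(boot, rel=0.15)

    def test_ci_contains_point_estimate(self, rng):
        x = rng.normal(0.8, 1, 40)
        y = rng.normal(0, 1, 40)
        res = auc_ci_delong(x, y)
        assert res.ci[0] <= res.auc <= res.ci[1]
        assert 0.0 <= res.ci[0] and res.ci[1] <= 1.0

    def test_null_type_one_error(self):
        rng = np.random.default_rng(99)
        hits = 0
        reps = 2000
        for _ in range(reps):
            res = auc_ci_delong(rng.normal(0, 1, 100), rng.normal(0, 1, 100))
            hits += res.p_vs_half < 0.05
        assert abs(hits / reps - 0.05) < 0.02


class TestPairedComparison:
    def test_identical_markers(self, rng):
        v = rng.normal(0, 1, 60)
        labels = (rng.random(60) < 0.5).astype(int)
        if labels.sum() < 2 or (1 - labels).sum() < 2:
            labels[:2], labels[-2:] = 1, 0
        res = compare_auc_paired(v, v, labels)
        assert res.delta == 0.0 and res.p == 1.0

    def test_antisymmetry(self, rng):
        a = rng.normal(0, 1, 80)
        b = rng.normal(0, 1, 80)
        labels = np.repeat([1, 0], 40)
        ab = compare_auc_paired(a, b, labels)
        ba = compare_auc_paired(b, a, labels)
        assert ab.delta == pytest.approx(-ba.delta)
        assert ab.p == pytest.approx(ba.p)

    def test_informative_vs_random(self, rng):
        labels = np.repeat([1, 0], 50)
        perfect = labels + rng.random(100) * 0.5  # separates perfectly
        noise = rng.normal(0, 1, 100)
        res = compare_auc_paired(perfect, noise, labels)
        assert res.delta > 0.3 and res.p < 0.001

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_auc_paired([1, 2], [1, 2, 3], [1, 0])


class TestOptimalCutoff:
    def exhaustive_best_j(self, x, y):
        best = -1.0
        for t in np.concatenate([x, y]):
            j = (x > t).mean() + (y <= t).mean() - 1
            best = max(best, j)
        return best

    def test_perfect_separation(self):
        curve = empirical_roc([5.0, 6.0], [1.0, 2.0])
        cutoff, j = optimal_cutoff(curve)
        assert j == pytest.approx(1.0)
        assert 2.0 <= cutoff.cutoff < 5.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            x = rng.normal(1, 1, 25)
            y = rng.normal(0, 1, 25)
            curve = empirical_roc(x, y)
            _, j = optimal_cutoff(curve)
            assert j == pytest.approx(self.exhaustive_best_j(x, y), abs=1e-12)

    def test_all_equal_uninformative(self):
        curve = empirical_roc([2.0, 2.0], [2.0, 2.0])
        _, j = optimal_cutoff(curve)
        assert j == pytest.approx(0.0)

    def test_tie_breaks_toward_higher_specificity(self):
        # J ties along a flat segment; the chosen threshold must sit at
        # the lowest-FPR end of the tie
        x = [3.0, 4.0]
        y = [1.0, 2.0]
        cutoff, j = optimal_cutoff(empirical_roc(x, y))
        assert j == pytest.approx(1.0)
        assert cutoff.cutoff == pytest.approx(2.0)


class TestConfusion:
    def test_partition(self, rng):
        v = rng.normal(0, 1, 50)
        labels = (rng.random(50) < 0.4).astype(int)
        c = confusion_at_cutoff(v, labels, MarkerCutoff("m", 0.5))
        assert c.total == 50
        assert c.n_cases == labels.sum()

    def test_perfect_table(self):
        c = confusion_at_cutoff([2, 2, 0.1, 0.1], [1, 1, 0, 0], MarkerCutoff("m", 1.0))
        assert (c.tp, c.fn, c.fp, c.tn) == (2, 0, 0, 2)

    def test_cutoff_above_max(self):
        c = confusion_at_cutoff([1.0, 2.0], [1, 0], MarkerCutoff("m", 10.0))
        assert c.tp == 0 and c.fp == 0

    def test_strict_inequality_at_cutoff(self):
        c = confusion_at_cutoff([1.0], [1], MarkerCutoff("m", 1.0))
        assert c.tp == 0 and c.fn == 1

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_cutoff([1.0, math.nan], [1, 0], MarkerCutoff("m", 1.0))


class TestMetrics:
    def test_hmmr_hcc_vs_nontumor_row(self):
        m = metrics_from_confusion(ConfusionCounts(tp=106, fn=27, fp=7, tn=79)).round2()
        assert m["sensitivity"] == 79.70
        assert m["specificity"] == 91.86
        assert m["accuracy"] == 84.47
        assert m["ppv"] == 93.81
        assert m["npv"] == 74.53
        assert m["odds_ratio"] == 44.31

    def test_triplet_panel_row(self):
        m = metrics_from_confusion(ConfusionCounts(tp=124, fn=8, fp=13, tn=73)).round2()
        assert m["plr"] == 6.21
        assert m["nlr"] == 0.07
        assert m["accuracy"] == 90.37
        assert m["odds_ratio"] == 87.04

    def test_perfect_table_flags_infinite_or(self):
        m = metrics_from_confusion(ConfusionCounts(tp=5, fn=0, fp=0, tn=5))
        assert m.sensitivity == m.specificity == m.accuracy == 100.0
        assert math.isinf(m.odds_ratio) and "odds_ratio" in m.flags

    def test_haldane_correction_finite(self):
        m = metrics_from_confusion(ConfusionCounts(tp=5, fn=0, fp=0, tn=5), haldane=True)
        assert math.isfinite(m.odds_ratio) and m.odds_ratio > 1

    def test_lr_odds_identity(self, rng):
        # OR = (+LR)/(-LR) whenever all four cells are positive
        for _ in range(50):
            tp, fn, fp, tn = rng.integers(1, 200, 4)
            m = metrics_from_confusion(ConfusionCounts(int(tp), int(fn), int(fp), int(tn)))
            assert m.odds_ratio == pytest.approx(m.plr / m.nlr, rel=1e-9)

    def test_reconstruction_round_trip(self):
        c = reconstruct_confusion(79.70, 91.86, 133, 86)
        assert (c.tp, c.fn, c.fp, c.tn) == (106, 27, 7, 79)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionCounts(0, 0, 1, 1))
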
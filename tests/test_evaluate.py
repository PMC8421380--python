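"""Evaluation battery: AUC oracles, decision curves, PR curves, cross-validation."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from prvscreen.evaluate import (
    DegenerateCohortError,
    ScoredCohort,
    auc_mann_whitney,
    decision_curve,
    net_benefit,
    ppv_at_prevalence,
    precision_recall,
    repeated_cv_auc,
    roc_auc,
    threshold_table,
)


def cohort(scores, labels):
    return ScoredCohort(np.asarray(scores, float), np.asarray(labels, bool))


def brute_force_auc(scores, labels):
    """Pairwise positive-vs-negative counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_small_enumerable_example(self):
        c = cohort([3, 5, 1, 2, 4], [1, 1, 0, 0, 0])
        assert auc_mann_whitney(c) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        c = cohort([10, 11, 1, 2], [1, 1, 0, 0])
        assert auc_mann_whitney(c) == 1.0

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(0)
        c = cohort(rng.normal(size=10_000), rng.random(10_000) < 0.4)
        assert auc_mann_whitney(c) == pytest.approx(0.5, abs=0.02)

    def test_matches_brute_force_pair_counting_including_ties(self):
        """Oracle equivalence on 1000 random cohorts (with tied scores)."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(4, 60))
            scores = rng.integers(0, 10, n).astype(float)  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            c = cohort(scores, labels)
            assert auc_mann_whitney(c) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_on_random_cohorts(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            scores = rng.normal(size=n)
            labels = rng.random(n) < 0.3
            if labels.all() or not labels.any():
                continue
            c = cohort(scores, labels)
            assert auc_mann_whitney(c) == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        a = auc_mann_whitney(cohort(scores, labels))
        b = auc_mann_whitney(cohort(np.exp(scores) + 3, labels))
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateCohortError):
            auc_mann_whitney(cohort([1, 2], [1, 1]))

    def test_delong_ci_matches_independent_reference(self):
        # reference interval computed with R's pROC (DeLong) on this fixture
        y = [1, 1, 1, 0, 0, 0, 0, 1, 0, 1]
        s = [3.2, 5.1, 2.2, 1.0, 2.0, 4.1, 0.5, 2.2, 3.3, 6.0]
        res = roc_auc(cohort(s, y))
        assert res.area == pytest.approx(0.76)
        assert res.ci_low == pytest.approx(0.4138013356, abs=1e-9)
        assert res.ci_high == pytest.approx(1.0)

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self):
        rng = np.random.default_rng(4)
        c = cohort(rng.normal(size=80) + rng.random(80), rng.random(80) < 0.4)
        r1 = roc_auc(c, ci_method="bootstrap", n_boot=200, seed=5)
        r2 = roc_auc(c, ci_method="bootstrap", n_boot=200, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.area <= r1.ci_high

    def test_roc_curve_is_monotone(self):
        rng = np.random.default_rng(6)
        c = cohort(rng.normal(size=60), rng.random(60) < 0.5)
        curve = roc_auc(c)
        assert np.all(np.diff(curve.x) >= 0) and np.all(np.diff(curve.y) >= 0)
        assert (curve.x[0], curve.y[0]) == (0.0, 0.0)
        assert (curve.x[-1], curve.y[-1]) == (1.0, 1.0)


class TestThresholdTable:
    def test_threshold_below_min_score_flags_everyone(self):
        c = cohort([3, 5, 1, 2, 4], [1, 1, 0, 0, 0])
        row = threshold_table(c, [0.0]).iloc[0]
        assert row["sensitivity"] == 1.0 and row["specificity"] == 0.0

    def test_f1_combines_sensitivity_and_ppv(self):
        c = cohort([1, 2, 3, 4], [0, 0, 1, 1])
        row = threshold_table(c, [2.5]).iloc[0]
        assert row["f1"] == 1.0  # sens 1, ppv 1
        # worked value: sens 0.8, ppv 0.5 -> 2*0.4/1.3
        from prvscreen.evaluate import _f1

        assert _f1(0.8, 0.5) == pytest.approx(0.6154, abs=1e-4)

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError):
            threshold_table(cohort([1, 2], [0, 1]), [])


class TestPpvAtPrevalence:
    @pytest.mark.parametrize(
        "sens, spec, prev, expected",
        [(0.9, 0.9, 0.5, 0.9), (0.9, 0.9, 0.1, 0.5), (0.7, 1.0, 0.2, 1.0)],
    )
    def test_worked_examples(self, sens, spec, prev, expected):
        assert ppv_at_prevalence(sens, spec, prev) == pytest.approx(expected)

    def test_arguments_validated(self):
        with pytest.raises(ValueError):
            ppv_at_prevalence(1.2, 0.5, 0.5)

    def test_identity_with_empirical_ppv_at_own_prevalence(self):
        """Bayes' rule at the cohort's own prevalence recovers the raw PPV."""
        rng = np.random.default_rng(7)
        scores = rng.normal(size=300) + 1.2 * (rng.random(300) < 0.3)
        labels = rng.random(300) < 0.3
        c = cohort(scores, labels)
        table = threshold_table(c, np.quantile(scores, [0.1, 0.3, 0.5, 0.7, 0.9]))
        for _, row in table.iterrows():
            if np.isnan(row["ppv"]):
                continue
            adj = ppv_at_prevalence(row["sensitivity"], row["specificity"], c.prevalence)
            assert adj == pytest.approx(row["ppv"], abs=1e-12)


class TestNetBenefit:
    def test_ten_extra_benefits_per_hundred(self):
        for pt in (0.05, 0.2, 0.5, 0.9):
            assert net_benefit(tp=10, fp=0, n=100, pt=pt) == pytest.approx(0.1)

    def test_treat_none_is_zero(self):
        assert net_benefit(0, 0, 50, 0.3) == 0.0

    def test_treat_all_at_even_odds_threshold(self):
        # prevalence 0.5 at pt = 1/3: 0.5 - 0.5 * 0.5
        assert net_benefit(tp=50, fp=50, n=100, pt=1 / 3) == pytest.approx(0.25)

    @pytest.mark.parametrize("pt", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_probability_bounds(self, pt):
        with pytest.raises(ValueError):
            net_benefit(1, 1, 10, pt)


class TestDecisionCurve:
    @pytest.fixture()
    def separable(self):
        rng = np.random.default_rng(8)
        labels = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        scores = np.r_[rng.uniform(10, 20, 50), rng.uniform(0, 5, 50)]
        return cohort(scores, labels)

    def test_treat_none_identically_zero(self, separable):
        res = decision_curve(separable)
        assert np.all(res.treat_none.y == 0.0)

    def test_treat_all_approaches_prevalence_at_small_pt(self, separable):
        res = decision_curve(separable, pt_grid=[1e-6])
        assert res.treat_all.y[0] == pytest.approx(separable.prevalence, abs=1e-5)

    def test_perfect_marker_dominates_references(self, separable):
        res = decision_curve(separable, pt_grid=np.arange(0.05, 0.951, 0.05))
        assert np.all(res.marker.y >= res.treat_all.y - 1e-9)
        assert np.all(res.marker.y >= -1e-9)
        assert np.allclose(res.marker.y, separable.prevalence, atol=1e-6)

    def test_no_marker_beats_the_ideal_marker(self):
        rng = np.random.default_rng(9)
        labels = rng.random(200) < 0.4
        scores = rng.normal(size=200) + labels
        c = cohort(scores, labels)
        pts = np.arange(0.05, 0.951, 0.05)
        res = decision_curve(c, pts)
        ideal = decision_curve(c, pts, probabilities=labels.astype(float))
        assert np.all(res.marker.y <= ideal.marker.y + 1e-9)

    def test_pt_grid_validated(self, separable):
        with pytest.raises(ValueError):
            decision_curve(separable, pt_grid=[0.0, 0.5])


class TestPrecisionRecall:
    def test_enumerated_sweep_points(self):
        c = cohort([3, 5, 1, 2, 4], [1, 1, 0, 0, 0])
        curve = precision_recall(c)
        pts = {(round(r, 6), round(p, 6)) for r, p in zip(curve.x, curve.y)}
        assert (0.5, 1.0) in pts  # threshold at score 5
        assert (1.0, round(2 / 3, 6)) in pts  # threshold at score 3

    def test_perfect_separation_area_one(self):
        c = cohort([10, 11, 12, 1, 2], [1, 1, 1, 0, 0])
        assert precision_recall(c).area == pytest.approx(1.0)

    def test_uninformative_scores_area_near_prevalence(self):
        rng = np.random.default_rng(10)
        c = cohort(rng.normal(size=5000), rng.random(5000) < 0.3)
        assert precision_recall(c).area == pytest.approx(0.3, abs=0.03)

    def test_prevalence_reweighting_lowers_precision_for_rarer_disease(self):
        rng = np.random.default_rng(11)
        labels = rng.random(400) < 0.4
        scores = rng.normal(size=400) + 2 * labels
        c = cohort(scores, labels)
        raw = precision_recall(c)
        adj = precision_recall(c, prevalence=0.10)
        assert adj.area < raw.area


class TestRepeatedCvAuc:
    def test_separable_cohort_has_unit_auc_everywhere(self):
        labels = np.r_[np.ones(40, bool), np.zeros(60, bool)]
        scores = np.r_[np.linspace(10, 20, 40), np.linspace(0, 5, 60)]
        res = repeated_cv_auc(cohort(scores, labels), k=5, reps=3, seed=1)
        assert res.mean_auc == 1.0
        assert res.interval == (1.0, 1.0)

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(12)
        c = cohort(rng.normal(size=200), rng.random(200) < 0.4)
        a = repeated_cv_auc(c, seed=7)
        b = repeated_cv_auc(c, seed=7)
        np.testing.assert_array_equal(a.fold_aucs, b.fold_aucs)

    def test_null_cohort_interval_contains_half(self):
        rng = np.random.default_rng(13)
        c = cohort(rng.normal(size=1000), rng.random(1000) < 0.4)
        res = repeated_cv_auc(c, seed=2)
        assert res.interval[0] < 0.5 < res.interval[1]

    def test_every_fold_contains_both_classes(self):
        labels = np.r_[np.ones(12, bool), np.zeros(88, bool)]
        scores = np.random.default_rng(14).normal(size=100)
        res = repeated_cv_auc(cohort(scores, labels), k=10, reps=2, seed=3)
        assert np.all(np.isfinite(res.fold_aucs))

    def test_tiny_or_imbalanced_cohorts_rejected(self):
        with pytest.raises(ValueError):
            repeated_cv_auc(cohort([1, 2, 3, 4], [0, 0, 1, 1]), k=10)
        labels = np.r_[np.ones(3, bool), np.zeros(97, bool)]
        with pytest.raises(ValueError):
            repeated_cv_auc(cohort(np.arange(100.0), labels), k=10)

    def test_cv_mean_consistent_with_single_split_on_synthetic_cohort(self, scored):
        c = scored("cv")
        single = auc_mann_whitney(c)
        res = repeated_cv_auc(c, k=10, reps=10, seed=4)
        assert res.interval[0] - 0.02 <= single <= res.interval[1] + 0.02
        assert res.mean_auc == pytest.approx(single, abs=0.03)
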
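"""Statistical evaluation: ROC/Youden oracles, bootstrap, logistic fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from diffanomaly.evaluate import (bootstrap_roc, fit_exam_logistic,
                                  malignancy_stratified_eval, roc_curve,
                                  threshold_sweep, youden_threshold)


def pair_count_auc(pos, neg):
    """Brute-force Mann-Whitney statistic: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Best J over every distinct classification (positive iff score > t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    distinct = np.unique(scores)
    cands = list(distinct) + [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    cands += [distinct[0] - 1, distinct[-1] + 1]
    best = -np.inf
    for t in cands:
        pred = scores > t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        best = max(best, sens + spec - 1.0)
    return best


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == 1.0
        # J = 1 inside the separating gap; threshold is the gap midpoint
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0
        assert roc.youden_threshold == pytest.approx(0.5)

    def test_all_ties_half_credit(self):
        roc = roc_curve([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auc == 0.5
        assert roc.sensitivity + roc.specificity - 1.0 == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(5, 25, size=2)
        # duplicate-prone grid to exercise tie handling
        pos = rng.choice(np.linspace(0, 1, 12), size=n_pos)
        neg = rng.choice(np.linspace(0, 1, 12), size=n_neg)
        roc = roc_curve(np.r_[pos, neg],
                        np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)])
        assert roc.auc == pytest.approx(pair_count_auc(pos, neg), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(100 + seed)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([0.1, 0.2], [1, 1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                    min_size=2, max_size=30),
           st.data())
    def test_auc_pair_count_property(self, scores, data):
        n = len(scores)
        labels = data.draw(st.lists(st.sampled_from([0, 1]), min_size=n,
                                    max_size=n))
        if sum(labels) in (0, n):
            return
        scores = np.array(scores)
        labels = np.array(labels)
        expected = pair_count_auc(scores[labels == 1], scores[labels == 0])
        assert roc_curve(scores, labels).auc == pytest.approx(expected, abs=1e-12)


class TestYouden:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 9), size=30)
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        roc = roc_curve(scores, labels)
        thr, sens, spec, fpr = youden_threshold(roc)
        assert sens + spec - 1.0 == pytest.approx(
            exhaustive_youden(scores, labels), abs=1e-12)
        # reported metrics are consistent with re-applying the threshold
        pred = scores > thr
        assert sens == pytest.approx(pred[labels == 1].mean())
        assert fpr == pytest.approx(pred[labels == 0].mean())
        assert spec == pytest.approx(1 - fpr)

    def test_tie_break_toward_higher_threshold(self):
        # J = 0 everywhere; the highest candidate threshold must be returned
        roc = roc_curve([0.2, 0.4, 0.2, 0.4], [0, 0, 1, 1])
        assert roc.youden_threshold >= 0.4


class TestBootstrapRoc:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        pos, neg = rng.normal(1, 1, 300), rng.normal(0, 1, 300)
        a = bootstrap_roc(pos, neg, n_per_group=128, n_replicates=10, seed=5)
        b = bootstrap_roc(pos, neg, n_per_group=128, n_replicates=10, seed=5)
        assert [r.auc for r in a.replicates] == [r.auc for r in b.replicates]
        assert a.ci == b.ci

    def test_single_replicate_degenerate_ci(self):
        rng = np.random.default_rng(1)
        out = bootstrap_roc(rng.normal(1, 1, 200), rng.normal(0, 1, 200),
                            n_per_group=50, n_replicates=1, seed=0)
        lo, hi = out.ci["auc"]
        assert lo == hi == out.replicates[0].auc

    def test_null_configuration_ci_contains_half(self):
        rng = np.random.default_rng(2)
        pool = rng.normal(size=600)
        out = bootstrap_roc(pool[:300], pool[300:], n_per_group=128,
                            n_replicates=10, seed=3)
        lo, hi = out.ci["auc"]
        assert lo <= 0.5 <= hi

    def test_small_pool_falls_back_to_replacement(self):
        rng = np.random.default_rng(3)
        out = bootstrap_roc(rng.normal(1, 1, 40), rng.normal(0, 1, 300),
                            n_per_group=128, n_replicates=3, seed=1)
        assert out.sampled_with_replacement
        assert all(r.n_pos == 128 for r in out.replicates)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            bootstrap_roc([], [0.1], seed=0)


def _test_nll(params, X, y):
    eta = X @ params
    return np.sum(np.logaddexp(0.0, eta)) - y @ eta


class TestExamLogistic:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_numerical_maximizer(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        score = rng.uniform(0, 1, n)
        scanner = rng.integers(0, 2, n)
        eta = -0.5 + 1.5 * score + 0.8 * scanner
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_exam_logistic(score, y, scanner)
        assert fit.converged
        X = np.column_stack([np.ones(n), score, scanner])
        ref = optimize.minimize(_test_nll, np.zeros(3), args=(X, y),
                                method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 1000}).x
        got = [fit.coefficients[k] for k in
               ("intercept", "exam_score", "scanner_indicator")]
        np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_label_symmetric_design_zero_coefficient(self):
        score = np.repeat(np.linspace(0.1, 0.9, 6), 2)
        labels = np.tile([0, 1], 6)
        scanner = np.zeros(12)
        fit = fit_exam_logistic(score, labels, scanner)
        assert abs(fit.coefficients["exam_score"]) < 1e-8

    def test_zero_variance_score_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_exam_logistic([0.5] * 8, [0, 1] * 4, [0] * 8)

    def test_complete_separation_flagged(self):
        score = np.r_[np.zeros(8), np.ones(8)]
        labels = np.r_[np.zeros(8, int), np.ones(8, int)]
        fit = fit_exam_logistic(score, labels, np.zeros(16))
        assert not fit.converged
        assert fit.diagnostic is not None
        assert not fit.score_significant

    def test_wald_p_consistent_with_z(self):
        from scipy.stats import norm
        rng = np.random.default_rng(7)
        n = 80
        score = rng.uniform(size=n)
        y = (rng.uniform(size=n) < 0.3 + 0.4 * score).astype(int)
        fit = fit_exam_logistic(score, y, rng.integers(0, 2, n))
        for k, z in fit.wald_z.items():
            assert fit.p_values[k] == pytest.approx(2 * norm.sf(abs(z)))
            lo, hi = fit.conf_int[k]
            assert lo <= fit.coefficients[k] <= hi


class TestThresholdSweep:
    def test_extreme_thresholds(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 0, 1, 1])
        table = threshold_sweep(scores, labels, thresholds=[0.0, 1.0])
        low, high = table.iloc[0], table.iloc[1]
        assert low.sensitivity == 1.0 and low.specificity == 0.0
        assert high.sensitivity == 0.0 and high.specificity == 1.0

    def test_hand_counted_confusion_cells(self):
        scores = np.array([0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75,
                           0.85, 0.95])
        labels = np.array([0, 0, 0, 1, 0, 1, 0, 1, 1, 1])
        table = threshold_sweep(scores, labels, thresholds=[0.5])
        row = table.iloc[0]
        # score > 0.5: indices 5..9 -> labels 1,0,1,1,1
        assert (row.tp, row.fp, row.tn, row.fn) == (4, 1, 4, 1)
        assert row.sensitivity == pytest.approx(0.8)
        assert row.specificity == pytest.approx(0.8)
        assert row.ppv == pytest.approx(4 / 5)
        assert row.npv == pytest.approx(4 / 5)

    def test_full_grid_shape(self):
        table = threshold_sweep([0.1, 0.9], [0, 1])
        assert len(table) == 9
        np.testing.assert_allclose(table.t_exam, np.arange(0.1, 0.95, 0.1))


class TestStratifiedEval:
    def test_empty_stratum_gives_na_table(self):
        scores = np.array([0.1, 0.9, 0.8, 0.2])
        grades = np.array([1, 2, 2, 1])  # no grade >= 3 present
        out = malignancy_stratified_eval(scores, grades, thresholds=[0.5])
        assert out["grade_3plus"].sensitivity.isna().all()
        assert not out["any_lesion"].sensitivity.isna().any()

    def test_all_grade3plus_matches_any_lesion_grouping(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        grades = np.array([1, 1, 4, 5])
        out = malignancy_stratified_eval(scores, grades, thresholds=[0.5])
        assert out["any_lesion"].equals(out["grade_3plus"])

    def test_regrouping_matches_recount_oracle(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(size=30)
        grades = rng.choice([1, 2, 3, 4, 5], size=30)
        out = malignancy_stratified_eval(scores, grades, thresholds=[0.4])
        row = out["grade_3plus"].iloc[0]
        labels = (grades >= 3).astype(int)
        pred = scores > 0.4
        assert row.tp == (pred & (labels == 1)).sum()
        assert row.tn == (~pred & (labels == 0)).sum()
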
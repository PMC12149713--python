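"""ROC/AUC, Youden cutoff, confusion metrics, DeLong test, decision curves."""

import numpy as np
import pytest

from habitatpipe.evaluation import (confusion_metrics, decision_curve,
                                    delong_test, reconstruct_confusion,
                                    roc_auc, youden_cutoff)


class TestROC:
    def test_perfect_ranking(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_pair_counting_example(self):
        # 3 of 4 positive/negative pairs correctly ordered
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == 0.75

    def test_all_ties_give_half(self):
        r = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert r.auc == 0.5

    def test_matches_sklearn_oracle_with_ties(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(100):
            scores = rng.integers(0, 5, 30).astype(float)  # heavy ties
            labels = rng.integers(0, 2, 30)
            if len(np.unique(labels)) < 2:
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_trapezoid_equivalence(self, rng):
        for _ in range(100):
            scores = rng.normal(size=40).round(1)
            labels = rng.integers(0, 2, 40)
            if len(np.unique(labels)) < 2:
                continue
            r = roc_auc(scores, labels)
            trap = np.trapezoid(r.tpr, r.fpr)
            assert r.auc == pytest.approx(trap, abs=1e-12)

    def test_ci_clipped_and_ordered(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestYouden:
    def test_separable_smallest_threshold(self):
        r = roc_auc([0.1, 0.2, 0.7, 0.9], [0, 0, 1, 1])
        thr, op = youden_cutoff(r)
        assert op["youden"] == 1.0
        assert thr == 0.7  # smallest separating candidate threshold

    def test_matches_exhaustive_scan(self, rng):
        scores = np.array([0.1, 0.3, 0.35, 0.5, 0.65, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 1])
        r = roc_auc(scores, labels)
        thr, op = youden_cutoff(r)
        best = -1
        for cand in np.unique(scores):
            pred = scores >= cand
            tpr = (pred & (labels == 1)).sum() / 3
            fpr = (pred & (labels == 0)).sum() / 3
            best = max(best, tpr - fpr)
        assert op["youden"] == pytest.approx(best)

    def test_constant_scores_zero_youden(self):
        r = roc_auc([0.4] * 8, [0, 1] * 4)
        _, op = youden_cutoff(r)
        assert op["youden"] == 0.0


class TestConfusionMetrics:
    def test_habitat_test_set_row(self):
        m = confusion_metrics(TP=8, FN=8, TN=21, FP=6)
        assert round(m.accuracy, 3) == 0.674
        assert round(m.balanced_accuracy, 3) == 0.639
        assert round(m.ppv, 3) == 0.571
        assert round(m.npv, 3) == 0.724
        assert round(m.mcc, 3) == 0.287

    def test_habitat_cf_test_set_row(self):
        m = confusion_metrics(TP=7, FN=9, TN=24, FP=3)
        assert round(m.mcc, 3) == 0.373

    def test_perfect_prediction(self):
        m = confusion_metrics(TP=5, FP=0, TN=5, FN=0)
        assert m.mcc == 1.0 and m.accuracy == 1.0

    def test_balanced_accuracy_identity(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            m = confusion_metrics(tp, fp, tn, fn)
            assert m.balanced_accuracy == pytest.approx(
                (m.sensitivity + m.specificity) / 2)

    def test_reconstruction_from_printed_rates(self):
        m = reconstruct_confusion(0.500, 0.778, n_pos=16, n_neg=27)
        assert (m.TP, m.FN, m.TN, m.FP) == (8, 8, 21, 6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)


class TestDeLong:
    def test_self_comparison_is_null(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:3], labels[-3:] = 1, 0
        res = delong_test(scores, scores, labels)
        assert res.difference == 0 and res.p_value == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        labels = np.r_[np.ones(20, int), np.zeros(30, int)]
        r1 = delong_test(a, b, labels)
        r2 = delong_test(b, a, labels)
        assert r1.difference == pytest.approx(-r2.difference)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_variance_close_to_bootstrap_oracle(self, rng):
        # 20-case sample: DeLong AUC variance vs stratified bootstrap
        labels = np.r_[np.ones(8, int), np.zeros(12, int)]
        scores = np.r_[rng.normal(1.0, 1, 8), rng.normal(0, 1, 12)]
        r = roc_auc(scores, labels)
        delong_var = r.auc_se ** 2
        pos, neg = scores[:8], scores[8:]
        boots = []
        for _ in range(10_000):
            bp = rng.choice(pos, 8)
            bn = rng.choice(neg, 12)
            wins = (bp[:, None] > bn[None, :]).sum() \
                + 0.5 * (bp[:, None] == bn[None, :]).sum()
            boots.append(wins / 96)
        boot_var = np.var(boots, ddof=1)
        assert delong_var == pytest.approx(boot_var, rel=0.15)

    def test_type_i_error_calibrated(self):
        labels = np.r_[np.ones(36, int), np.zeros(64, int)]
        rejections = 0
        n_rep = 2000
        r = np.random.default_rng(2024)
        for _ in range(n_rep):
            a = r.normal(size=100)
            b = r.normal(size=100)
            if delong_test(a, b, labels).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestDecisionCurve:
    def test_treat_none_is_zero(self, rng):
        p = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        dca = decision_curve(p, labels)
        assert (dca.treat_none == 0).all()

    def test_treat_all_closed_form(self):
        # prevalence 0.364 emulating the test cohort; pt = 0.2
        labels = np.r_[np.ones(16, int), np.zeros(28, int)]  # 16/44 = 0.364
        dca = decision_curve(np.linspace(0, 1, 44), labels,
                             thresholds=[0.2])
        prev = 16 / 44
        assert dca.treat_all[0] == pytest.approx(prev - (1 - prev) * 0.25)
        assert dca.treat_all[0] == pytest.approx(0.205, abs=5e-4)

    def test_perfect_predictor_reaches_prevalence(self):
        labels = np.r_[np.ones(10, int), np.zeros(15, int)]
        probs = labels.astype(float)
        dca = decision_curve(probs, labels)
        np.testing.assert_allclose(dca.net_benefit, dca.prevalence)
        assert (dca.net_benefit <= dca.prevalence + 1e-12).all()

    def test_pt_one_rejected(self):
        labels = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError):
            decision_curve([0.2, 0.4, 0.6, 0.8], labels, thresholds=[1.0])
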
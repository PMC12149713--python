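"""Staged feature selection: ICC, normalization, redundancy, LASSO, RFE."""

import numpy as np
import pandas as pd
import pytest

from habitatpipe.selection import (SelectionReport, ZScoreNormalizer,
                                   choose_rfe_target, icc_2_1, icc_filter,
                                   lasso_alpha_grid, lasso_select,
                                   pearson_filter, rfe_select, run_selection,
                                   zscore_normalize)


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc_2_1(x) == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0) + 50.0])
        assert icc_2_1(x) < 1.0

    def test_matches_independent_anova_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (12, 2)) + rng.normal(0, 2, (12, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile([0, 1], 12),
            "score": x.ravel()})
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        row = ref["Type"].isin(["ICC2", "ICC(A,1)"])  # label differs by version
        want = float(ref.loc[row, "ICC"].iloc[0])
        assert icc_2_1(x) == pytest.approx(want, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.full((5, 2), 3.0))

    def test_low_bias_on_known_variance_components(self, rng):
        # subject sd 1, rater-noise sd 0.5 -> true ICC = 1/(1+0.25) = 0.8
        true_icc = 1.0 / 1.25
        vals = []
        for _ in range(500):
            subj = rng.normal(0, 1, (30, 1))
            x = subj + rng.normal(0, 0.5, (30, 2))
            vals.append(icc_2_1(x))
        assert abs(np.mean(vals) - true_icc) < 0.02


class TestICCFilter:
    def test_identical_tables_keep_everything(self, rng):
        t = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        retained, _ = icc_filter(t, t.copy())
        assert retained == list("abcde")

    def test_noise_feature_dropped(self, rng):
        base = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        drops = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            other = base + r.normal(0, 0.05, base.shape)
            other["b"] = r.normal(size=30)  # independent noise
            retained, _ = icc_filter(base, other)
            drops += "b" not in retained
        assert drops >= 19  # dropped with probability >= 0.95

    def test_column_mismatch_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(5, 2)), columns=["x", "y"])
        b = pd.DataFrame(rng.normal(size=(5, 2)), columns=["x", "z"])
        with pytest.raises(ValueError):
            icc_filter(a, b)


class TestZScore:
    def test_training_columns_standardized(self, rng):
        t = pd.DataFrame(rng.normal(3, 2, size=(40, 4)))
        out, stats = zscore_normalize(t)
        np.testing.assert_allclose(out.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(0, ddof=0), 1, atol=1e-12)

    def test_test_rows_use_training_stats(self, rng):
        train = pd.DataFrame(rng.normal(0, 1, size=(50, 2)), columns=["a", "b"])
        test = train + 5.0
        norm = ZScoreNormalizer().fit(train)
        out = norm.transform(test)
        assert out["a"].mean() > 1.0  # shifted data is not recentred

    def test_constant_column_dropped_and_reported(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        norm = ZScoreNormalizer().fit(t)
        assert norm.dropped_ == ["b"]
        assert list(norm.transform(t).columns) == ["a"]


class TestPearsonFilter:
    def test_duplicate_column_deduplicated(self, rng):
        a = rng.normal(size=50)
        t = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=50)})
        assert pearson_filter(t) == ["a", "c"]

    def test_strict_inequality_boundary(self, rng):
        # construct |r| ~ 0.89 < cutoff: both retained
        a = rng.normal(size=2000)
        b = 0.89 * a + np.sqrt(1 - 0.89 ** 2) * rng.normal(size=2000)
        t = pd.DataFrame({"a": a, "b": b})
        r = abs(np.corrcoef(a, b)[0, 1])
        assert r < 0.9
        assert pearson_filter(t) == ["a", "b"]

    def test_retained_set_matches_exhaustive_scan(self, rng):
        a = rng.normal(size=300)
        t = pd.DataFrame({
            "a": a, "b": a + rng.normal(0, 0.05, 300),
            "c": rng.normal(size=300),
            "d": -a + rng.normal(0, 0.05, 300),
            "e": rng.normal(size=300)})
        kept = pearson_filter(t)
        corr = t[kept].corr().abs().to_numpy()
        assert (corr[~np.eye(len(kept), dtype=bool)] <= 0.9).all()
        # greedy order: first of each correlated group survives
        assert kept == ["a", "c", "e"]


class TestLasso:
    def test_exponential_grid_spacing(self):
        grid = lasso_alpha_grid(num=3)
        np.testing.assert_allclose(grid, [0.005, np.sqrt(0.005 * 0.05), 0.05],
                                   rtol=1e-12)
        assert grid[0] == 0.005 and grid[-1] == 0.05

    def test_recovers_planted_support(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(200, 23)),
                             columns=[f"x{i}" for i in range(23)])
            eta = 1.5 * X["x0"] + 1.5 * X["x1"] - 1.5 * X["x2"]
            y = (r.random(200) < 1 / (1 + np.exp(-eta))).astype(int)
            selected, alpha = lasso_select(X, y, seed=seed)
            hits += {"x0", "x1", "x2"} <= set(selected)
            assert 0.005 <= alpha <= 0.05
        assert hits >= 18  # >= 90% of runs

    def test_huge_alpha_empty_selection_passthrough(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 5)))
        y = rng.integers(0, 2, 50)
        selected, _ = lasso_select(X, y, alphas=[1e6])
        assert selected == list(X.columns)  # documented pass-through

    def test_too_few_rows_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            lasso_select(X, [0, 1, 0])


class TestRFE:
    def test_identity_when_target_is_all(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, 40)
        selected, _ = rfe_select(X, y, 4)
        assert selected == list("abcd")

    def test_informative_feature_survives(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            X = pd.DataFrame(r.normal(size=(300, 11)),
                             columns=[f"x{i}" for i in range(11)])
            eta = 2.0 * X["x5"]
            y = (r.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
            selected, _ = rfe_select(X, y, 1, seed=seed)
            hits += selected == ["x5"]
        assert hits >= 18

    def test_invalid_targets_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        y = rng.integers(0, 2, 20)
        for bad in (0, 4):
            with pytest.raises(ValueError):
                rfe_select(X, y, bad)


class TestFullChain:
    def _table(self, rng, n=100, p=30, informative=False):
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{i}" for i in range(p)])
        if informative:
            eta = 2.0 * X["f0"] - 2.0 * X["f1"]
        else:
            eta = np.zeros(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return X, y

    def test_stagewise_monotone_subsets(self, rng):
        X, y = self._table(rng, informative=True)
        report, _ = run_selection(X, y, rfe_target=4, seed=0)
        names = list(report.stages)
        for earlier, later in zip(names, names[1:]):
            assert set(report.stages[later]) <= set(report.stages[earlier])

    def test_chain_reproducible_from_seed(self, rng):
        X, y = self._table(rng, informative=True)
        r1, _ = run_selection(X, y, rfe_target=4, seed=7)
        r2, _ = run_selection(X, y, rfe_target=4, seed=7)
        assert r1.stages == r2.stages and r1.lasso_alpha == r2.lasso_alpha

    def test_null_data_no_selection_leakage(self):
        """With y independent of X the held-out AUC of the selected model
        stays near chance: selection is fit on training rows only."""
        from habitatpipe.evaluation import roc_auc
        from habitatpipe.models import ModelSpec, predict_scores, train_classifier

        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(100, 114)),
                             columns=[f"f{i}" for i in range(114)])
            y = (r.random(100) < 0.36).astype(int)
            tr = np.zeros(100, dtype=bool)
            tr[:70] = True
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[~tr])) < 2:
                continue
            report, norm = run_selection(X[tr], y[tr], rfe_target=5, seed=seed)
            Xn = norm.transform(X)[report.selected]
            model = train_classifier(Xn[tr], y[tr],
                                     ModelSpec(variant="Habitats", seed=seed))
            aucs.append(roc_auc(predict_scores(model, Xn[~tr]), y[~tr]).auc)
        assert 0.35 <= np.mean(aucs) <= 0.65


def test_choose_rfe_target_prefers_informative_count(rng):
    X = pd.DataFrame(rng.normal(size=(150, 8)),
                     columns=[f"f{i}" for i in range(8)])
    eta = 2.0 * X["f0"] + 2.0 * X["f1"]
    y = (rng.random(150) < 1 / (1 + np.exp(-eta))).astype(int)
    t = choose_rfe_target(X, y, targets=range(2, 7), seed=0)
    assert 2 <= t <= 6
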
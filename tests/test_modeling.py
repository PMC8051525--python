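import numpy as np
import pandas as pd
import pytest

from eegfx import (CARTRegression, fit_cart, cv_select_cp, one_se_select,
                   pearson_with_t, run_method_comparison, ScoreTable)
from eegfx.modeling import UndefinedCorrelationWarning, _risk, _n_leaves

from _oracles import (oracle_grow, oracle_prune_sequence, trees_match,
                      oracle_risk)


class TestFit:
    def test_constant_response_root_only(self, rng):
        X = rng.standard_normal((8, 3))
        with pytest.warns(UserWarning, match="constant"):
            res = fit_cart(X, np.full(8, 2.5))
        assert res.n_leaves == 1
        assert res.tree_.mean == 2.5

    def test_clean_step_single_split(self):
        # y = 1 below x1 = 0, y = 2 above; noise-free, n = 8
        x1 = np.array([-4.0, -3.0, -2.0, -1.0, 1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([x1, np.zeros(8)])
        y = np.where(x1 < 0, 1.0, 2.0)
        res = fit_cart(X, y)
        t = res.tree_
        assert t.feature == 0
        assert -1.0 < t.threshold < 1.0
        assert t.left.is_leaf and t.right.is_leaf
        assert {t.left.mean, t.right.mean} == {1.0, 2.0}

    @pytest.mark.parametrize("case", range(20))
    def test_matches_exhaustive_oracle(self, case):
        rng = np.random.default_rng(100 + case)
        X = rng.uniform(size=(12, 6))
        y = rng.standard_normal(12)
        res = fit_cart(X, y, minsplit=4)
        oracle = oracle_grow(X, y, minsplit=4)
        assert trees_match(res.tree_, oracle, res.model.feature_names)

    @pytest.mark.parametrize("case", range(10))
    def test_pruning_sequence_matches_oracle(self, case):
        rng = np.random.default_rng(300 + case)
        X = rng.uniform(size=(12, 6))
        y = rng.standard_normal(12)
        res = fit_cart(X, y, minsplit=4)
        oracle_seq = oracle_prune_sequence(oracle_grow(X, y, minsplit=4))
        ours = [(a, _n_leaves(t), _risk(t)) for a, t in res._seq]
        assert len(ours) == len(oracle_seq)
        for (a1, l1, r1), (a2, l2, r2) in zip(ours, oracle_seq):
            assert a1 == pytest.approx(a2, abs=1e-10)
            assert l1 == l2
            assert r1 == pytest.approx(r2, abs=1e-10)

    def test_sklearn_training_sse_cross_check(self, rng):
        # same greedy objective => same training SSE of the full tree
        from sklearn.tree import DecisionTreeRegressor
        X = rng.uniform(size=(12, 6))
        y = rng.standard_normal(12)
        res = fit_cart(X, y, minsplit=4)
        sk = DecisionTreeRegressor(min_samples_split=4, min_samples_leaf=1,
                                   random_state=0).fit(X, y)
        ours = np.sum((y - res.predict(X)) ** 2)
        theirs = np.sum((y - sk.predict(X)) ** 2)
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_missing_values_rejected(self, rng):
        X = rng.uniform(size=(8, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            CARTRegression(X, np.arange(8.0))


class TestPruning:
    def test_cp_table_monotone(self, rng):
        X = rng.uniform(size=(12, 6))
        y = rng.standard_normal(12)
        res = fit_cart(X, y)
        t = res.cp_table
        assert (t["cp"].diff().dropna() <= 0).all()
        assert (t["n_leaves"].diff().dropna() >= 0).all()
        assert (t["rel_error"].diff().dropna() <= 1e-12).all()

    def test_tree_size_nonincreasing_in_cp(self, rng):
        X = rng.uniform(size=(12, 6))
        y = rng.standard_normal(12)
        res = fit_cart(X, y)
        sizes = [res.prune(cp).n_leaves
                 for cp in np.linspace(0, 1.2 * res.cp_table["cp"].max(), 25)]
        assert (np.diff(sizes) <= 0).all()

    def test_one_se_never_larger_than_min_error_tree(self, rng):
        X = rng.uniform(size=(12, 6))
        y = rng.standard_normal(12)
        res = fit_cart(X, y)
        cv = res.cross_validate(k=10, seed=1)
        cp_1se = one_se_select(cv)
        cp_min = float(cv.loc[cv["xerror"].idxmin(), "cp"])
        assert res.prune(cp_1se).n_leaves <= res.prune(cp_min).n_leaves


class TestOneSERule:
    def test_hand_constructed_table(self):
        table = pd.DataFrame({"cp": [1.0, 0.1, 0.01],
                              "xerror": [1.0, 0.5, 0.48],
                              "xstd": [0.1, 0.1, 0.1]})
        assert one_se_select(table) == 0.1

    def test_single_row(self):
        table = pd.DataFrame({"cp": [0.3], "xerror": [1.0], "xstd": [0.2]})
        assert one_se_select(table) == 0.3

    def test_ties_favor_parsimony(self):
        table = pd.DataFrame({"cp": [1.0, 0.1, 0.01],
                              "xerror": [0.7, 0.7, 0.7],
                              "xstd": [0.0, 0.0, 0.0]})
        assert one_se_select(table) == 1.0

    def test_cv_select_cp_runs(self, rng):
        X = rng.uniform(size=(12, 4))
        y = X[:, 0] * 3 + 0.1 * rng.standard_normal(12)
        res = fit_cart(X, y)
        cp = cv_select_cp(res, k=10, seed=0)
        assert cp in res.cp_table["cp"].values

    def test_loo_fallback_warns(self, rng):
        X = rng.uniform(size=(6, 3))
        y = rng.standard_normal(6)
        res = fit_cart(X, y)
        with pytest.warns(UserWarning, match="leave-one-out"):
            res.cross_validate(k=10, seed=0)


class TestPredict:
    def test_root_tree_constant(self, rng):
        X = rng.uniform(size=(8, 2))
        y = rng.standard_normal(8)
        res = fit_cart(X, y).prune(np.inf)
        pred = res.predict(X)
        np.testing.assert_allclose(pred, y.mean())

    def test_full_tree_reproduces_separated_response(self, rng):
        # distinct feature values and minsplit 2 let the full tree isolate
        # every row: predictions on the training rows equal y exactly
        X = rng.uniform(size=(10, 3))
        y = rng.standard_normal(10)
        res = fit_cart(X, y, minsplit=2)
        np.testing.assert_allclose(res.predict(X), y, atol=1e-12)

    def test_threshold_routing_convention(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        res = fit_cart(X, y, minsplit=2)
        thr = res.tree_.threshold
        # a row exactly at the threshold goes right (>= convention)
        assert res.predict(np.array([[thr]]))[0] == res.tree_.right.mean

    def test_missing_used_feature_named(self, rng):
        X = pd.DataFrame(rng.uniform(size=(10, 2)), columns=["a", "b"])
        y = X["a"].to_numpy() * 2
        res = fit_cart(X, y, minsplit=2)
        with pytest.raises(KeyError, match="a"):
            res.predict(pd.DataFrame({"b": [0.5]}))

    def test_dump_and_summary_text(self, rng):
        X = pd.DataFrame(rng.uniform(size=(10, 2)), columns=["f1", "f2"])
        y = X["f1"].to_numpy()
        res = fit_cart(X, y, minsplit=4)
        dump = res.dump_tree()
        assert "f1 <" in dump and "leaf" in dump
        assert "complexity table" in res.summary()


class TestPearson:
    # printed (r, t) worked examples at n = 12 (t = r sqrt(10)/sqrt(1-r^2))
    @pytest.mark.parametrize("r,t_expected", [
        (0.6, 2.37), (0.57, 2.2), (-0.72, -3.28), (0.64, 2.63),
    ])
    def test_t_closed_form_reproduces_reported_values(self, r, t_expected):
        rng = np.random.default_rng(0)
        # build vectors with this exact correlation via Gram-Schmidt
        x = rng.standard_normal(12)
        e = rng.standard_normal(12)
        e -= e.mean() + 0  # center
        x = (x - x.mean()) / x.std()
        e = e - (e @ x) / (x @ x) * x
        e /= np.sqrt(e @ e / 12)
        y = r * x + np.sqrt(1 - r ** 2) * e
        res = pearson_with_t(x, y)
        assert res.r == pytest.approx(r, abs=1e-10)
        assert res.df == 10
        ndigits = 2 if abs(round(res.t, 2) - t_expected) < abs(
            round(res.t, 1) - t_expected) else 1
        assert round(res.t, ndigits) == pytest.approx(t_expected)

    def test_perfect_correlation_capped(self):
        x = np.arange(12.0)
        res = pearson_with_t(x, 2 * x + 1)
        assert res.r == 1.0
        assert np.isinf(res.t)
        assert res.p == 0.0

    def test_constant_vector_undefined(self):
        with pytest.warns(UndefinedCorrelationWarning):
            res = pearson_with_t(np.full(12, 1.0), np.arange(12.0))
        assert np.isnan(res.r) and np.isnan(res.p)
        assert res.df == 10

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_with_t(np.arange(2.0), np.arange(2.0))

    def test_p_value_matches_scipy(self, rng):
        from scipy import stats
        x = rng.standard_normal(12)
        y = x + rng.standard_normal(12)
        res = pearson_with_t(x, y)
        r_sp, p_sp = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_sp)
        assert res.p == pytest.approx(p_sp)


class TestMethodComparison:
    def _tables(self, rng, driven=True):
        n, p = 12, 8
        latent = rng.uniform(0.5, 2.5, size=n)
        def feats():
            X = rng.standard_normal((n, p))
            X[:, 2] = latent + 0.05 * rng.standard_normal(n)
            return pd.DataFrame(
                X, index=[f"S{i:02d}" for i in range(n)],
                columns=[f"f{j}" for j in range(p)])
        train, test = feats(), feats()
        scores = pd.DataFrame({
            "TPM": 10 + 4 * latent + 0.3 * rng.standard_normal(n),
            "ACH": rng.standard_normal(n),
        }, index=train.index)
        return train, test, ScoreTable(scores)

    def test_driven_subscore_recovered(self, rng):
        train, test, scores = self._tables(rng)
        report = run_method_comparison(train, test, scores, seed=3,
                                       method="synth")
        assert report.frame.loc["TPM", "r"] > 0.6
        assert "f2" in report.frame.loc["TPM", "used_features"]
        assert set(report.frame.index) == {"TPM", "ACH"}

    def test_report_row_per_subscore(self, rng):
        train, test, scores = self._tables(rng)
        report = run_method_comparison(train, test, scores,
                                       subscores=("TPM",), seed=3)
        assert list(report.frame.index) == ["TPM"]
        assert report.summary()

    def test_misaligned_tables_rejected(self, rng):
        train, test, scores = self._tables(rng)
        with pytest.raises(ValueError, match="feature name"):
            run_method_comparison(train, test.iloc[:, ::-1], scores, seed=0)
        with pytest.raises(ValueError, match="subject"):
            run_method_comparison(train, test.iloc[::-1], scores, seed=0)

    def test_missing_values_imputed_with_train_median(self, rng):
        train, test, scores = self._tables(rng)
        train.iloc[0, 5] = np.nan
        test.iloc[3, 5] = np.nan
        report = run_method_comparison(train, test, scores, seed=3)
        assert np.isfinite(report.frame.loc["TPM", "r"])
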
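"""Modeling-protocol contracts: feature assembly, normalization/imputation,
stratified splitting, elastic-net limits, permutation testing, importance."""
import numpy as np
import pandas as pd
import pytest

import sefpredict as sp
from sefpredict.modeling import ElasticNetPoint, _neg_rmse


@pytest.fixture(scope="module")
def fmatrix(feature_cohort):
    sef, clinical, _ = feature_cohort
    return sp.assemble_features(clinical, sef=sef, feature_set="sef")


class TestAssemble:
    def test_sef_set_is_96_plus_hamd(self, fmatrix):
        assert fmatrix.X.shape[1] == 97
        assert list(fmatrix.X.columns)[-1] == "baseline_hamd"
        assert fmatrix.X.columns[0] == "Fp1_delta_theta_power"
        assert "Fp1_beta_duration" in fmatrix.X.columns

    def test_column_order_deterministic(self, feature_cohort):
        sef, clinical, _ = feature_cohort
        a = sp.assemble_features(clinical, sef=sef, feature_set="sef")
        b = sp.assemble_features(clinical, sef=sef, feature_set="sef")
        assert list(a.X.columns) == list(b.X.columns)
        pd.testing.assert_frame_equal(a.X, b.X)

    def test_missing_subject_row_kept_as_nan(self, feature_cohort):
        sef, clinical, _ = feature_cohort
        sef2 = sef[sef.subject_id != "sub-003"]
        fm = sp.assemble_features(clinical, sef=sef2, feature_set="sef")
        assert fm.X.loc["sub-003"].drop("baseline_hamd").isna().all()

    def test_empty_cell_nan_feature(self, feature_cohort):
        sef, clinical, _ = feature_cohort
        sef2 = sef.copy()
        mask = (sef2.subject_id == "sub-000") & (sef2.channel == "Fp1") & (sef2.band == "beta")
        sef2.loc[mask, ["mean_duration_s", "mean_freq_span_hz", "mean_peak_power_fom"]] = np.nan
        fm = sp.assemble_features(clinical, sef=sef2, feature_set="sef")
        assert np.isnan(fm.X.loc["sub-000", "Fp1_beta_duration"])

    def test_unknown_feature_set_rejected(self, feature_cohort):
        sef, clinical, _ = feature_cohort
        with pytest.raises(ValueError):
            sp.assemble_features(clinical, sef=sef, feature_set="everything")


class TestNormalizeImpute:
    def test_no_missing_is_identity_after_unzscore(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((10, 4)), columns=list("abcd"))
        tr = sp.FeatureTransform(k=2).fit(X)
        Z = tr.transform(X)
        # imputation untouched; z-scoring invertible
        back = Z * X.std(ddof=0) + X.mean()
        pd.testing.assert_frame_equal(back, X, check_exact=False, atol=1e-12)

    def test_knn_imputation_matches_brute_force(self):
        # 3 subjects, one NaN: value = mean of the 2 nearest rows' entries
        X = pd.DataFrame(
            {"a": [0.0, 1.0, 10.0], "b": [0.0, 1.0, 10.0], "c": [np.nan, 4.0, 8.0]}
        )
        tr = sp.FeatureTransform(k=2).fit(X)
        Z = tr.transform(X)
        mean, sd = X.mean(), X.std(ddof=0)
        z_c = (X["c"] - mean["c"]) / sd["c"]
        expected = (z_c[1] + z_c[2]) / 2  # the only other rows
        assert Z.loc[0, "c"] == pytest.approx(expected)

    def test_constant_column_zeroed(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0, 3.0]})
        Z = sp.FeatureTransform(k=2).fit(X).transform(X)
        assert (Z["a"] == 0).all()

    def test_train_statistics_unaffected_by_test_rows(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame(rng.standard_normal((12, 3)), columns=list("abc"))
        tr = sp.FeatureTransform(k=2).fit(train)
        test1 = pd.DataFrame(rng.standard_normal((4, 3)), columns=list("abc"))
        test2 = test1 * 1000.0
        out_train_1 = tr.transform(train)
        tr.transform(test2)  # must not mutate the fitted statistics
        out_train_2 = tr.transform(train)
        pd.testing.assert_frame_equal(out_train_1, out_train_2)

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            sp.FeatureTransform(k=2).fit(X)


class TestSplit:
    def test_82_subjects_split_sizes(self, fmatrix):
        train, test = sp.stratified_split(fmatrix, seed=0)
        assert {len(train), len(test)} in ({54, 28}, {55, 27})
        assert len(set(train) & set(test)) == 0

    def test_responder_proportion_preserved(self, fmatrix):
        strata = fmatrix.strata.to_numpy().astype(bool)
        for seed in range(5):
            train, test = sp.stratified_split(fmatrix, seed=seed)
            n_resp = strata.sum()
            for idx in (train, test):
                expected = n_resp * len(idx) / len(strata)
                assert abs(strata[idx].sum() - expected) <= 1

    def test_same_seed_same_membership(self, fmatrix):
        a = sp.stratified_split(fmatrix, seed=3)
        b = sp.stratified_split(fmatrix, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_empty_stratum_rejected(self, fmatrix):
        fm = sp.FeatureMatrix(
            X=fmatrix.X, y=fmatrix.y,
            strata=pd.Series(False, index=fmatrix.strata.index), feature_set="sef")
        with pytest.raises(ValueError):
            sp.stratified_split(fm)


class TestElasticNetLimits:
    def _toy(self, n=40, p=6, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        w = np.array([2.0, -1.0, 0.5, 0.0, 0.0, 3.0])
        y = X @ w + noise * rng.standard_normal(n)
        return X, y, w

    def test_alpha_zero_recovers_noiseless_coefficients(self):
        X, y, w = self._toy()
        Xd = pd.DataFrame(X)
        grid = sp.GridSpec(alphas=(0.0, 3.0), l1_ratios=(0.5,), fit_intercept=(False,))
        folds = sp.make_cv_folds(np.arange(40) % 2, seed=0)
        best, model, _ = sp.grid_search_fit(Xd, pd.Series(y), folds, grid)
        assert best["alpha"] == 0.0
        np.testing.assert_allclose(model.coef_, w, atol=1e-4)

    def test_ridge_closed_form_match(self):
        X, y, _ = self._toy(noise=0.5)
        alpha = 2.0
        model = ElasticNetPoint(alpha=alpha, l1_ratio=0.0, fit_intercept=False).fit(X, y)
        n = len(y)
        closed = np.linalg.solve(X.T @ X + alpha * n * np.eye(X.shape[1]), X.T @ y)
        np.testing.assert_allclose(model.coef_, closed, rtol=1e-6)

    def test_lasso_large_alpha_all_zero(self):
        X, y, _ = self._toy(noise=0.5)
        model = ElasticNetPoint(alpha=1e4, l1_ratio=1.0, fit_intercept=True).fit(X, y)
        assert np.all(model.coef_ == 0)

    def test_single_point_grid_selected(self):
        X, y, _ = self._toy(noise=1.0)
        grid = sp.GridSpec(alphas=(3.0,), l1_ratios=(0.5,), fit_intercept=(False,))
        folds = sp.make_cv_folds(np.arange(40) % 2, seed=1)
        best, _, table = sp.grid_search_fit(pd.DataFrame(X), pd.Series(y), folds, grid)
        assert best == {"alpha": 3.0, "l1_ratio": 0.5, "fit_intercept": False}
        assert len(table) == 1

    def test_grid_must_contain_reference_point(self):
        with pytest.raises(ValueError):
            sp.GridSpec(alphas=(1.0,), l1_ratios=(0.5,), fit_intercept=(False,))


class TestEvaluate:
    def test_perfect_predictions(self):
        class Identity:
            def predict(self, X):
                return np.asarray(X)[:, 0]
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        out = sp.evaluate(Identity(), X, pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert out["nrmse"] == 0.0
        assert out["r2"] == pytest.approx(1.0)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_constant_predictions_degenerate(self):
        class Const:
            def predict(self, X):
                return np.full(len(X), 5.0)
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = sp.evaluate(Const(), X, pd.Series([1.0, 2.0, 6.0]))
        assert out["r2"] <= 0.0
        assert np.isnan(out["pearson_r"])

    def test_four_point_toy_matches_manual_rmse(self):
        class Shift:
            def predict(self, X):
                return np.asarray(X)[:, 0] + 1.0
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0]})
        y = pd.Series([0.0, 3.0, 2.0, 3.0])
        out = sp.evaluate(Shift(), X, y)
        manual = -np.sqrt(np.mean([(1 - 0) ** 2, (2 - 3) ** 2, (3 - 2) ** 2, (4 - 3) ** 2]))
        assert out["nrmse"] == pytest.approx(manual)


class TestPermutation:
    def test_p_value_bounds(self, fmatrix):
        fm = sp.normalize_and_impute(fmatrix)
        folds = sp.make_cv_folds(fm.strata.to_numpy(), seed=0)
        res = sp.permutation_test({"alpha": 3.0, "l1_ratio": 0.5, "fit_intercept": False},
                                  fm.X, fm.y, folds, n_perm=39, seed=0)
        assert 1 / 40 <= res.p_value <= 1.0
        assert res.null_scores.size == 39

    def test_planted_effect_detected(self, fmatrix):
        fm = sp.normalize_and_impute(fmatrix)
        folds = sp.make_cv_folds(fm.strata.to_numpy(), seed=1)
        res = sp.permutation_test({"alpha": 3.0, "l1_ratio": 0.5, "fit_intercept": True},
                                  fm.X, fm.y, folds, n_perm=99, seed=1)
        assert res.p_value <= 0.05
        assert res.observed > res.null_scores.mean()


class TestImportance:
    def _fit_toy(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((n, 8)),
                         columns=[f"f{i}" for i in range(8)])
        y = pd.Series(3.0 * X["f2"] + 0.3 * rng.standard_normal(n))
        model = ElasticNetPoint(alpha=0.01, l1_ratio=0.5, fit_intercept=False).fit(X, y)
        return model, X, y

    def test_dominant_feature_ranked_first_across_seeds(self):
        wins = 0
        for seed in range(10):
            model, X, y = self._fit_toy(seed)
            imp = sp.permutation_importance(model, X, y, n_repeats=5, seed=seed)
            wins += imp.iloc[0]["feature"] == "f2"
        assert wins >= 9

    def test_zero_coefficient_feature_near_zero_importance(self):
        model, X, y = self._fit_toy(3)
        zeroed = [f for f, c in zip(X.columns, model.coef_) if abs(c) < 1e-8]
        imp = sp.permutation_importance(model, X, y, n_repeats=5, seed=0)
        for f in zeroed:
            val = imp.set_index("feature").loc[f, "importance"]
            assert abs(val) < 1e-6

    def test_pure_noise_column_negligible(self):
        rng = np.random.default_rng(7)
        model, X, y = self._fit_toy(7)
        X2 = X.assign(noise=rng.standard_normal(len(X)))
        model2 = ElasticNetPoint(alpha=0.01, l1_ratio=0.5, fit_intercept=False).fit(X2, y)
        imp = sp.permutation_importance(model2, X2, y, n_repeats=10, seed=7)
        val = imp.set_index("feature").loc["noise", "importance"]
        dominant = imp.set_index("feature").loc["f2", "importance"]
        assert abs(val) < 0.05 * abs(dominant)


class TestProtocol:
    def test_deterministic_reports(self, fmatrix):
        rep1 = sp.run_model_protocol(fmatrix, seed=11, n_perm=25,
                                     n_importance_repeats=3)
        rep2 = sp.run_model_protocol(fmatrix, seed=11, n_perm=25,
                                     n_importance_repeats=3)
        assert rep1.to_json() == rep2.to_json()

    def test_report_fields_sane(self, fmatrix):
        rep = sp.run_model_protocol(fmatrix, seed=2, n_perm=25,
                                    n_importance_repeats=3)
        assert rep.n_train + rep.n_test == 82
        assert rep.train_nrmse <= 0 and rep.test_nrmse <= 0
        assert 1 / 26 <= rep.perm_train["p_value"] <= 1.0
        assert rep.best_params["alpha"] in (0.1, 0.3, 1.0, 3.0, 10.0)
        assert len(rep.coefficients) == 97
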
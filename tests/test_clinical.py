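"""Hierarchical regression, stepwise AIC, nested CV: oracles and hygiene."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fixelpipe.clinical import (
    _ols_report, hierarchical_regression, nested_cv_predict, predict_ols,
    stepwise_aic, univariate_screen,
)
from fixelpipe.errors import DegenerateFitError, RankError


def exhaustive_best_subset_aic(y, X):
    """Brute-force all-subsets AIC oracle."""
    n = len(y)
    best_aic, best_set = np.inf, ()
    for k in range(len(X.columns) + 1):
        for subset in itertools.combinations(sorted(X.columns), k):
            M = np.column_stack([np.ones(n)]
                                + [X[c].to_numpy() for c in subset])
            beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
            rss = float(((y - M @ beta) ** 2).sum())
            aic = n * np.log(rss / n) + 2 * M.shape[1]
            if aic < best_aic:
                best_aic, best_set = aic, subset
    return best_aic, set(best_set)


class TestOlsReport:
    def test_matches_statsmodels(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(size=n)
        rep = _ols_report(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert rep.r2 == pytest.approx(ref.rsquared)
        assert rep.adjusted_r2 == pytest.approx(ref.rsquared_adj)
        assert rep.F == pytest.approx(ref.fvalue)
        assert np.allclose(rep.beta, ref.params)
        assert np.allclose(rep.p_values, ref.pvalues[1:])
        assert rep.rmse == pytest.approx(np.sqrt(ref.ssr / n))

    def test_adjusted_r2_and_rmse_closed_form(self, rng):
        n, k = 50, 4
        X = pd.DataFrame(rng.normal(size=(n, k)),
                         columns=[f"f{i}" for i in range(k)])
        y = rng.normal(size=n)
        rep = _ols_report(X, y)
        assert rep.adjusted_r2 == pytest.approx(
            1 - (1 - rep.r2) * (n - 1) / (n - k - 1))
        pred = predict_ols(rep, X)
        assert rep.rmse == pytest.approx(
            np.sqrt(np.mean((y - pred) ** 2)))

    def test_standardized_beta_scale_invariant(self, rng):
        n = 80
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = X @ [0.5, -0.2, 0.0] + rng.normal(size=n)
        rep1 = _ols_report(X, y.to_numpy())
        X2 = X.copy()
        X2["a"] = X2["a"] * 37.5
        rep2 = _ols_report(X2, y.to_numpy())
        assert np.allclose(rep1.beta_standardized, rep2.beta_standardized)
        assert rep1.r2 == pytest.approx(rep2.r2)
        assert rep1.aic == pytest.approx(rep2.aic)
        assert np.allclose(predict_ols(rep1, X), predict_ols(rep2, X2))

    def test_perfect_fit_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20)})
        y = 2.0 * X["a"].to_numpy() + 1.0
        with pytest.raises(DegenerateFitError):
            _ols_report(X, y)


class TestUnivariateScreen:
    def test_feature_equal_outcome_r_one(self, rng):
        y = rng.normal(size=30)
        out = univariate_screen(pd.DataFrame({"f": y}), y)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_five_point_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        out = univariate_screen(pd.DataFrame({"x": x}), y)
        r_hand = np.sum((x - 3) * (y - 3)) / np.sqrt(
            np.sum((x - 3) ** 2) * np.sum((y - 3) ** 2))
        assert out["r"].iloc[0] == pytest.approx(r_hand)

    def test_null_pass_rate_near_alpha(self, rng):
        hits = []
        for _ in range(300):
            X = pd.DataFrame({"f": rng.normal(size=100)})
            y = rng.normal(size=100)
            hits.append(univariate_screen(X, y)["p"].iloc[0] < 0.05)
        assert abs(np.mean(hits) - 0.05) < 0.035

    def test_matches_scipy_pearson(self, rng):
        import scipy.stats as st
        X = pd.DataFrame(rng.normal(size=(40, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = rng.normal(size=40)
        out = univariate_screen(X, y)
        for i, c in enumerate(X.columns):
            r, p = st.pearsonr(X[c], y)
            assert out["r"].iloc[i] == pytest.approx(r)
            assert out["p"].iloc[i] == pytest.approx(p)


class TestStepwiseAic:
    def test_no_candidates_intercept_only(self, rng):
        y = rng.normal(size=30)
        trace, rep = stepwise_aic(y, pd.DataFrame(index=range(30)))
        assert trace.steps == [] and trace.final_features == []
        assert rep.predictors == []

    def test_true_feature_recovered(self, rng):
        # the true predictor is always kept; the noise predictor survives
        # AIC with probability P(chi2_1 > 2) ~ 0.157, so exact recovery of
        # {x1} happens at ~84% of replicates
        exact = 0
        for _ in range(60):
            x1 = rng.normal(size=50)
            x2 = rng.normal(size=50)
            y = 2.0 * x1 + rng.normal(size=50)
            X = pd.DataFrame({"x1": x1, "x2": x2})
            trace, _ = stepwise_aic(y, X)
            assert "x1" in trace.final_features
            exact += trace.final_features == ["x1"]
        assert 0.70 <= exact / 60 <= 0.95

    def test_trace_aic_strictly_decreasing(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = (X["f0"] - X["f3"]).to_numpy() + rng.normal(size=60)
        trace, rep = stepwise_aic(y, X)
        aics = [a for _, _, a in trace.steps]
        assert all(b < a for a, b in zip(aics, aics[1:]))
        assert rep.aic == pytest.approx(trace.final_aic)

    def test_local_optimality_and_exhaustive_match(self, rng):
        match, total = 0, 30
        for _ in range(total):
            n, k = 60, 6
            X = pd.DataFrame(rng.normal(size=(n, k)),
                             columns=[f"f{i}" for i in range(k)])
            beta = rng.choice([0.0, 0.0, 0.5, -0.5], size=k)
            y = X.to_numpy() @ beta + rng.normal(size=n)
            trace, rep = stepwise_aic(y, X)
            # single-step local optimality, always
            for f in X.columns:
                if f in trace.final_features:
                    alt = [c for c in trace.final_features if c != f]
                else:
                    alt = sorted(trace.final_features + [f])
                alt_rep = _ols_report(X[alt], y)
                assert alt_rep.aic >= rep.aic - 1e-10
            best_aic, best_set = exhaustive_best_subset_aic(y, X)
            if set(trace.final_features) == best_set:
                match += 1
        assert match >= int(0.9 * total)


class TestHierarchical:
    def _blocks(self, rng, n=200, signal="block1"):
        b1 = pd.DataFrame({
            "age": rng.normal(48, 10, n), "sex": rng.integers(0, 2, n),
            "education_high": rng.integers(0, 2, n),
            "symptom_duration": rng.normal(14, 8, n),
        }).astype(float)
        b2 = pd.DataFrame({
            "NWMV": rng.normal(670, 35, n), "NDGMV": rng.normal(56, 7, n),
            "lesion_load": rng.normal(14, 10, n),
        })
        b3 = pd.DataFrame(rng.normal(size=(n, 5)),
                          columns=[f"tract{i}" for i in range(5)])
        if signal == "block1":
            y = 0.05 * b1["age"] + rng.normal(size=n)
        else:
            y = 0.5 * b3["tract2"] + rng.normal(size=n)
        return y.to_numpy(), b1, b2, b3

    def test_block1_only_outcome_keeps_no_fixel_feature(self, rng):
        none_kept = 0
        for _ in range(20):
            y, b1, b2, b3 = self._blocks(rng, signal="block1")
            res = hierarchical_regression(y, b1, b2, b3)
            assert res.delta_r2[1] < 0.05 and res.delta_r2[2] < 0.05
            none_kept += not res.retained_features
        assert none_kept >= 15

    def test_fixel_signal_recovered_with_correct_sign(self, rng):
        hits = 0
        for _ in range(20):
            y, b1, b2, b3 = self._blocks(rng, n=300, signal="tract")
            res = hierarchical_regression(y, b1, b2, b3)
            if "tract2" in res.retained_features:
                rep = res.block_reports[2]
                beta = rep.beta[1:][rep.predictors.index("tract2")]
                hits += beta > 0
        assert hits >= 19

    def test_collinear_duplicate_named(self, rng):
        y, b1, b2, b3 = self._blocks(rng)
        b2["NWMV_copy"] = b2["NWMV"]
        with pytest.raises(RankError, match="NWMV"):
            hierarchical_regression(y, b1, b2, b3)

    def test_flag_when_no_feature_passes(self, rng):
        y, b1, b2, b3 = self._blocks(rng, signal="block1")
        # outcome independent of block3 features and alpha impossible
        res = hierarchical_regression(y, b1, b2, b3, screen_alpha=1e-12)
        assert res.no_feature_passed
        assert res.block_reports[2].predictors == \
            res.block_reports[1].predictors


def _cv_data(rng, n=320, n_null=18, r2=0.5):
    X = pd.DataFrame(rng.normal(size=(n, n_null + 2)),
                     columns=[f"f{i}" for i in range(n_null + 2)])
    signal = 0.6 * X["f0"] + 0.4 * X["f1"]
    noise_sd = signal.std() * np.sqrt((1 - r2) / r2)
    y = signal + rng.normal(0, noise_sd, n)
    return X, y.to_numpy()


class TestNestedCv:
    def test_deterministic_given_seed(self, rng):
        X, y = _cv_data(rng)
        r1 = nested_cv_predict(X, y, seed=11)
        r2 = nested_cv_predict(X, y, seed=11)
        assert r1.consistent_features == r2.consistent_features
        assert np.array_equal(r1.test_index, r2.test_index)
        assert r1.test_rmse == r2.test_rmse and r1.test_r == r2.test_r

    def test_true_features_in_consistent_set(self, rng):
        X, y = _cv_data(rng)
        res = nested_cv_predict(X, y, seed=5)
        assert {"f0", "f1"} <= set(res.consistent_features)
        assert not res.empty_consistent_set
        assert res.test_r > 0.5

    def test_pure_noise_yields_empty_set_flag(self, rng):
        X = pd.DataFrame(rng.normal(size=(320, 20)),
                         columns=[f"f{i}" for i in range(20)])
        y = rng.normal(size=320)
        res = nested_cv_predict(X, y, seed=1)
        assert res.empty_consistent_set
        assert res.final_model is None

    def test_test_rows_disjoint_from_folds(self, rng):
        X, y = _cv_data(rng)
        res = nested_cv_predict(X, y, seed=3)
        test = set(res.test_index.tolist())
        for fold in res.fold_assignments:
            assert not (test & set(fold.tolist()))

    def test_feature_rescaling_keeps_selection_and_fit(self, rng):
        X, y = _cv_data(rng)
        res1 = nested_cv_predict(X, y, seed=2)
        X2 = X.copy()
        X2["f0"] = X2["f0"] * 10.0
        res2 = nested_cv_predict(X2, y, seed=2)
        assert res1.consistent_features == res2.consistent_features
        assert res1.test_rmse == pytest.approx(res2.test_rmse)
        assert res1.test_r == pytest.approx(res2.test_r)
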
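"""Cumulative-link model: likelihood, fitting, inference, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from rcstroke.exceptions import (
    ComparisonError,
    DegenerateOutcomeError,
    InputError,
)
from rcstroke.ordinal import (
    CumulativeLinkModel,
    CumulativeLinkResults,
    DesignSpec,
    build_design,
    lrt_compare,
)

from conftest import simulate_ordinal


# ----------------------------------------------------------------------
# design construction
# ----------------------------------------------------------------------

class TestBuildDesign:
    def test_interaction_column_is_product(self):
        df = pd.DataFrame({"y": [0, 1, 2], "dwiv": [10.0, 1.0, 2.0],
                           "n_rc": [2, 0, 3]})
        spec = DesignSpec("y", ("dwiv", "n_rc"), (("dwiv", "n_rc"),))
        _, X, _, names = build_design(df, spec)
        assert names == ["dwiv", "n_rc", "dwiv:n_rc"]
        np.testing.assert_allclose(X[:, 2], [20.0, 0.0, 6.0])

    def test_gapped_levels_collapse_to_ranks(self):
        df = pd.DataFrame({"y": [0, 1, 2, 4, 4, 1], "x": np.arange(6.0)})
        y, _, levels, _ = build_design(df, DesignSpec("y", ("x",)))
        np.testing.assert_array_equal(levels, [0, 1, 2, 4])
        np.testing.assert_array_equal(y, [0, 1, 2, 3, 3, 1])

    def test_absent_column_raises(self):
        df = pd.DataFrame({"y": [0, 1], "x": [1.0, 2.0]})
        with pytest.raises(InputError, match="absent"):
            build_design(df, DesignSpec("y", ("x", "zz")))

    def test_missing_values_raise_with_rows(self):
        df = pd.DataFrame({"y": [0, 1, 0], "x": [1.0, np.nan, 2.0]})
        with pytest.raises(InputError, match="missing values"):
            build_design(df, DesignSpec("y", ("x",)))

    def test_constant_outcome_raises(self):
        df = pd.DataFrame({"y": [1, 1, 1], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateOutcomeError):
            build_design(df, DesignSpec("y", ("x",)))

    def test_duplicate_terms_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            DesignSpec("y", ("x", "x"))


# ----------------------------------------------------------------------
# likelihood
# ----------------------------------------------------------------------

class TestLoglikelihood:
    def test_coin_flip_likelihood(self):
        # two levels, beta = 0, threshold 0: every observation has p = 1/2
        y = np.array([0, 1] * 10)
        X = np.ones((20, 1))
        m = CumulativeLinkModel(y, X)
        assert m.loglike([0.0], [0.0]) == pytest.approx(20 * np.log(0.5))

    def test_single_observation_contribution(self):
        y = np.array([1, 0])  # need 2 levels; check the first row's term
        X = np.array([[0.3], [0.0]])
        m = CumulativeLinkModel(y, X)
        th, b = 0.4, 1.2
        # P(Y=high) = 1 - F(th - x b) for row 0; P(Y=low) = F(th) for row 1
        expected = np.log(1 - expit(th - 0.3 * b)) + np.log(expit(th))
        assert m.loglike([b], [th]) == pytest.approx(expected, rel=1e-12)

    def test_matches_bruteforce_probabilities(self, rng):
        # direct per-observation probability oracle on a random instance
        n, J = 20, 3
        y = rng.integers(0, J, n)
        y[:J] = np.arange(J)  # ensure all levels observed
        X = rng.standard_normal((n, 2))
        beta = np.array([0.5, -0.3])
        th = np.array([-0.4, 0.9])
        m = CumulativeLinkModel(y, X)
        total = 0.0
        for i in range(n):
            eta = X[i] @ beta
            cdf = np.concatenate([[0.0], expit(th - eta), [1.0]])
            total += np.log(cdf[y[i] + 1] - cdf[y[i]])
        assert m.loglike(beta, th) == pytest.approx(total, rel=1e-12)

    def test_nonmonotone_thresholds_rejected(self):
        m = CumulativeLinkModel(np.array([0, 1, 2]), np.ones((3, 1)))
        with pytest.raises(InputError, match="increasing"):
            m.loglike([0.0], [1.0, -1.0])


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

class TestFit:
    def test_intercept_only_thresholds_are_cumulative_logits(self):
        # counts (10, 20, 30): theta_1 = logit(1/6), theta_2 = logit(1/2) = 0
        y = np.repeat([0, 1, 2], [10, 20, 30])
        res = CumulativeLinkModel(y, np.empty((60, 0))).fit()
        np.testing.assert_allclose(
            res.thresholds, [logit(10 / 60), 0.0], atol=1e-8
        )
        assert res.converged

    def test_two_by_two_closed_form_log_odds_ratio(self):
        # J=2 CLM is logistic regression; the 2x2 MLE is the sample log OR
        y = np.repeat([0, 1, 0, 1], [30, 10, 10, 30])
        x = np.repeat([0.0, 0.0, 1.0, 1.0], [30, 10, 10, 30])
        res = CumulativeLinkModel(y, x[:, None]).fit()
        assert res.params[0] == pytest.approx(np.log(9.0), abs=1e-6)

    def test_binary_outcome_equals_logistic_regression(self, rng):
        # J=2 equivalence against an independent logistic oracle, 50 datasets
        import statsmodels.api as sm

        for _ in range(50):
            n = rng.integers(40, 120)
            X = rng.standard_normal((n, 2))
            eta = X @ np.array([0.8, -0.4])
            y = (rng.random(n) < expit(eta)).astype(int)
            if y.min() == y.max():
                continue
            res = CumulativeLinkModel(y, X).fit()
            glm = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
            # theta_1 - x beta gives P(low); logistic intercept = -theta_1
            np.testing.assert_allclose(res.params, glm.params[1:], atol=1e-6)
            np.testing.assert_allclose(-res.thresholds[0], glm.params[0],
                                       atol=1e-6)

    def test_matches_statsmodels_ordered_model(self, cohort344):
        # independent general-purpose implementation on the same likelihood
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        X = cohort344[["age", "dwiv_cc", "n_rc"]].to_numpy()
        y = cohort344["mrs"].to_numpy()
        res = CumulativeLinkModel(y, X).fit()
        sm_res = OrderedModel(y, X, distr="logit").fit(
            method="bfgs", disp=0, gtol=1e-10, maxiter=500
        )
        np.testing.assert_allclose(res.params, sm_res.params[:3], atol=1e-5)
        np.testing.assert_allclose(res.llf, sm_res.llf, atol=1e-6)
        np.testing.assert_allclose(res.bse, sm_res.bse[:3], rtol=1e-4)

    def test_aic_identity_exact(self, cohort344, rng):
        y, X = simulate_ordinal(rng, 150, [0.5], [-1.0, 0.0, 1.0])
        for res in (
            CumulativeLinkModel(y, X).fit(),
            CumulativeLinkModel(cohort344["mrs"].to_numpy(),
                                cohort344[["age"]].to_numpy()).fit(),
        ):
            assert res.aic - (-2.0 * res.llf + 2.0 * res.k_params) == 0.0
            assert res.k_params == len(res.params) + res.observed_levels.size - 1

    def test_thresholds_monotone_and_vcov_psd(self, cohort344):
        res = CumulativeLinkModel(
            cohort344["nihss"].to_numpy(),
            cohort344[["age", "sex", "dwiv_cc", "n_rc"]].to_numpy(),
        ).fit()
        assert np.all(np.diff(res.thresholds) > 0)
        np.testing.assert_allclose(res.vcov, res.vcov.T, atol=1e-10)
        assert np.linalg.eigvalsh(res.vcov).min() > -1e-8

    def test_covariate_shift_moves_thresholds_not_slopes(self, rng):
        y, X = simulate_ordinal(rng, 300, [0.7, -0.2], [-0.5, 0.8])
        res1 = CumulativeLinkModel(y, X).fit()
        X2 = X.copy()
        X2[:, 0] += 5.0
        res2 = CumulativeLinkModel(y, X2).fit()
        np.testing.assert_allclose(res1.params, res2.params, atol=1e-6)
        np.testing.assert_allclose(
            res2.thresholds - res1.thresholds, 5.0 * res1.params[0], atol=1e-6
        )

    def test_likelihood_dominance_over_generating_parameters(self, rng):
        beta, th = [0.6, -0.3], [-1.0, 0.5, 1.5]
        for _ in range(10):
            y, X = simulate_ordinal(rng, 200, beta, th)
            m = CumulativeLinkModel(y, X)
            res = m.fit()
            assert res.llf >= m.loglike(beta, th) - 1e-9

    def test_consistency_error_shrinks_with_n(self, rng):
        beta, th = [0.5], [-0.5, 0.5]
        rmse = []
        for n, reps in ((200, 30), (2000, 10), (20000, 5)):
            est = []
            for _ in range(reps):
                y, X = simulate_ordinal(rng, n, beta, th)
                est.append(CumulativeLinkModel(y, X).fit().params[0])
            rmse.append(np.sqrt(np.mean((np.asarray(est) - 0.5) ** 2)))
        assert rmse[0] > rmse[1] > rmse[2]
        assert rmse[2] < 0.02

    def test_separation_warns_and_flags(self):
        # perfectly separated binary data diverges
        y = np.array([0] * 10 + [1] * 10)
        x = np.array([-1.0] * 10 + [1.0] * 10)
        with pytest.warns(UserWarning, match="separation"):
            res = CumulativeLinkModel(y, x[:, None]).fit()
        assert not res.converged

    def test_small_n_warns(self):
        y = np.array([0, 1, 2, 0, 1])
        X = np.random.default_rng(0).standard_normal((5, 3))
        with pytest.warns(UserWarning, match="unstable"):
            try:
                CumulativeLinkModel(y, X).fit()
            except Exception:
                pass


# ----------------------------------------------------------------------
# inference on the fitted model
# ----------------------------------------------------------------------

class TestInference:
    def test_zero_coefficient_gives_unit_odds_ratio(self, rng):
        y, X = simulate_ordinal(rng, 200, [0.0], [-0.5, 0.5])
        res = CumulativeLinkModel(y, X).fit()
        tab = res.odds_ratios()
        assert (tab["ci_low"] <= tab["or"]).all()
        assert (tab["or"] <= tab["ci_high"]).all()
        assert (tab[["or", "ci_low", "ci_high"]] > 0).all().all()

    def test_or_transform_is_exp_of_coefficient(self, rng):
        y, X = simulate_ordinal(rng, 300, [0.6, -0.2], [-0.5, 0.5])
        res = CumulativeLinkModel(y, X).fit()
        tab = res.odds_ratios(alpha=0.05)
        np.testing.assert_allclose(tab["or"], np.exp(res.params))
        np.testing.assert_allclose(
            tab["ci_low"], np.exp(res.params - 1.959963984540054 * res.bse)
        )

    def test_predict_sums_to_one(self, cohort344):
        res = CumulativeLinkModel(
            cohort344["mrs"].to_numpy(), cohort344[["age", "n_rc"]].to_numpy()
        ).fit()
        probs = res.predict(cohort344[["age", "n_rc"]].to_numpy()[:25])
        assert probs.shape == (25, res.observed_levels.size)
        assert (probs > 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_intercept_only_predict_recovers_frequencies(self):
        y = np.repeat([0, 1, 2], [15, 30, 55])
        res = CumulativeLinkModel(y, np.empty((100, 0))).fit()
        np.testing.assert_allclose(
            res.predict(np.empty((1, 0)))[0], [0.15, 0.30, 0.55], atol=1e-7
        )

    def test_binary_predict_is_logistic(self, rng):
        y, X = simulate_ordinal(rng, 200, [0.8], [0.3])
        res = CumulativeLinkModel(y, X).fit()
        p_high = res.predict(X)[:, 1]
        np.testing.assert_allclose(
            p_high, expit(X[:, 0] * res.params[0] - res.thresholds[0]),
            atol=1e-12,
        )


# ----------------------------------------------------------------------
# nested-model comparison
# ----------------------------------------------------------------------

class TestLRT:
    def test_identical_models_give_zero_chi2(self, rng):
        y, X = simulate_ordinal(rng, 150, [0.4], [-0.5, 0.5])
        res = CumulativeLinkModel(y, X).fit()
        cmp_ = lrt_compare(res, res)
        assert cmp_.chi2 == 0.0
        assert cmp_.p == 1.0

    def test_nested_comparison_df_and_positivity(self, cohort344):
        y = cohort344["mrs"].to_numpy()
        res_small = CumulativeLinkModel(y, cohort344[["age"]].to_numpy(),
                                        ["age"]).fit()
        res_big = CumulativeLinkModel(
            y, cohort344[["age", "n_rc"]].to_numpy(), ["age", "n_rc"]
        ).fit()
        cmp_ = lrt_compare(res_small, res_big)
        assert cmp_.df == 1
        assert cmp_.chi2 >= 0.0
        assert 0.0 <= cmp_.p <= 1.0

    def test_non_nested_specs_rejected(self, cohort344):
        y = cohort344["mrs"].to_numpy()
        res_a = CumulativeLinkModel(y, cohort344[["age"]].to_numpy(), ["age"]).fit()
        res_b = CumulativeLinkModel(y, cohort344[["n_rc"]].to_numpy(),
                                    ["n_rc"]).fit()
        with pytest.raises(ComparisonError, match="not nested"):
            lrt_compare(res_a, res_b)

    def test_null_rejection_rate_is_alpha(self, rng):
        # extra term truly zero: LRT p-values should be uniform
        rejections = 0
        reps = 200
        for _ in range(reps):
            y, X = simulate_ordinal(rng, 80, [0.5, 0.0], [-0.5, 0.5])
            res_full = CumulativeLinkModel(y, X).fit()
            res_nested = CumulativeLinkModel(y, X[:, :1], ["x1"]).fit()
            if lrt_compare(res_nested, res_full).p < 0.05:
                rejections += 1
        # binomial(200, 0.05): 3 sd band around 10
        assert 1 <= rejections <= 20
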
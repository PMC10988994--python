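"""2SLS/OLS estimation, Hausman comparison, strata, controls, pooling."""

import numpy as np
import pandas as pd
import pytest

from mrcea.cohort import GeneratorParams, generate_cohort
from mrcea.mr import (MREstimate, StratumSpec, fit_2sls, fit_ols,
                      hausman_test, impute_and_pool, negative_control,
                      scale_qaly, stratified_mr)
from mrcea.prs import build_prs


@pytest.fixture(scope="module")
def fitted(prostate_like):
    _, cohort, dosages, weights, _ = prostate_like
    prs = build_prs(dosages, weights)
    covs = cohort.covariate_matrix()
    y = cohort.df["annual_cost"].to_numpy()
    x = cohort.df["cancer"].to_numpy(float)
    return cohort, prs, covs, y, x


class TestTwoStageLeastSquares:
    def test_no_covariates_equals_wald_ratio(self, fitted):
        _, prs, _, y, x = fitted
        res = fit_2sls(y, x, prs)
        z = prs.scores
        wald = np.cov(y, z)[0, 1] / np.cov(x, z)[0, 1]
        assert abs(res.beta - wald) / abs(wald) < 1e-10

    def test_outcome_equal_to_exposure_recovers_unity(self, fitted):
        _, prs, covs, _, x = fitted
        res = fit_2sls(x, x, prs, covs)
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert np.max(np.abs(res.resid)) < 1e-8

    def test_matches_statsmodels_iv2sls_coefficients(self, fitted):
        from statsmodels.sandbox.regression.gmm import IV2SLS
        _, prs, covs, y, x = fitted
        res = fit_2sls(y, x, prs, covs)
        n = y.size
        X = np.column_stack([np.ones(n), x, covs])
        Z = np.column_stack([np.ones(n), prs.scores, covs])
        ref = IV2SLS(y, X, instrument=Z).fit()
        np.testing.assert_allclose(res.params, ref.params, rtol=1e-8)

    def test_instrument_rescaling_leaves_beta_unchanged(self, fitted):
        _, prs, covs, y, x = fitted
        r1 = fit_2sls(y, x, prs, covs)
        r2 = fit_2sls(y, x, prs.scores * 1000.0, covs)
        assert abs(r2.beta - r1.beta) / abs(r1.beta) < 1e-9
        assert r2.se == pytest.approx(r1.se, rel=1e-9)

    def test_first_stage_f_reported_and_strong(self, fitted):
        _, prs, covs, y, x = fitted
        res = fit_2sls(y, x, prs, covs)
        assert res.first_stage_f > 30
        assert res.method == "2sls"
        assert res.ci95 == pytest.approx(
            (res.beta - 1.96 * res.se, res.beta + 1.96 * res.se))

    def test_degenerate_inputs_raise(self, fitted):
        _, prs, covs, y, x = fitted
        with pytest.raises(ValueError, match="zero variance"):
            fit_2sls(y, x, np.ones_like(y), covs)
        bad = np.column_stack([covs, covs[:, 0]])  # collinear block
        with pytest.raises(np.linalg.LinAlgError):
            fit_2sls(y, x, prs, bad)
        with pytest.raises(ValueError, match="non-finite"):
            fit_2sls(np.where(y > 500, np.nan, y), x, prs, covs)


class TestLinearModel:
    def test_null_when_exposure_independent(self, rng):
        n = 5_000
        y = rng.normal(0, 1, n)
        x = rng.binomial(1, 0.3, n).astype(float)
        res = fit_ols(y, x)
        assert abs(res.beta) <= 2 * res.se
        assert res.first_stage_f is None

    def test_matches_statsmodels_hc1(self, fitted):
        import statsmodels.api as sm
        _, _, covs, y, x = fitted
        res = fit_ols(y, x, covs)
        X = sm.add_constant(np.column_stack([x, covs]))
        ref = sm.OLS(y, X).fit(cov_type="HC1")
        np.testing.assert_allclose(res.params, ref.params, rtol=1e-8)
        assert res.se == pytest.approx(ref.bse[1], rel=1e-8)

    def test_duplicating_rows_keeps_beta_shrinks_se_root2(self, rng):
        n = 2_000
        x = rng.binomial(1, 0.4, n).astype(float)
        y = 2.0 * x + rng.normal(0, 1, n)
        r1 = fit_ols(y, x)
        r2 = fit_ols(np.tile(y, 2), np.tile(x, 2))
        assert r2.beta == pytest.approx(r1.beta, rel=1e-12)
        assert r2.se == pytest.approx(r1.se / np.sqrt(2), rel=1e-2)

    def test_summary_table_contents(self, fitted):
        _, prs, covs, y, x = fitted
        res = fit_2sls(y, x, prs, covs, outcome_label="annual_cost",
                       exposure_label="cancer")
        s = res.summary()
        assert s.loc[0, "outcome"] == "annual_cost"
        assert s.loc[0, "beta"] == pytest.approx(res.beta)
        assert "first_stage_f" in s.columns
        est = res.estimate
        assert isinstance(est, MREstimate) and est.method == "2sls"


class TestHausman:
    def _pair(self, beta_iv, se_iv, beta_ols, se_ols, n=100):
        iv = MREstimate(beta_iv, se_iv,
                        (beta_iv - 1.96 * se_iv, beta_iv + 1.96 * se_iv),
                        50.0, n, "y", "x", "2sls")
        ols = MREstimate(beta_ols, se_ols,
                         (beta_ols - 1.96 * se_ols, beta_ols + 1.96 * se_ols),
                         None, n, "y", "x", "ols")
        return iv, ols

    def test_identical_estimates_give_zero_statistic(self):
        iv, ols = self._pair(5.0, 2.0, 5.0, 1.0)
        h = hausman_test(iv, ols)
        assert h.statistic == 0.0 and h.p_value == 1.0 and h.df == 1

    def test_nonpositive_variance_difference_clamped_with_warning(self):
        iv, ols = self._pair(5.0, 1.0, 4.0, 2.0)
        with pytest.warns(UserWarning, match="clamped"):
            h = hausman_test(iv, ols)
        assert h.statistic == 0.0 and h.p_value == 1.0

    def test_mismatched_fits_rejected(self):
        iv, _ = self._pair(5.0, 2.0, 4.0, 1.0)
        _, ols = self._pair(4.0, 2.0, 4.0, 1.0, n=99)
        with pytest.raises(ValueError, match="different fits"):
            hausman_test(iv, ols)
        with pytest.raises(ValueError, match="expects"):
            hausman_test(ols, iv)

    def test_detects_strong_confounding(self):
        """With heavy confounding OLS is biased and 2SLS is not; the test
        should reject in well over half of replicates at n = 20,000."""
        rej = 0
        for s in range(40):
            p = GeneratorParams.realistic(
                20_000, seed=4_000 + s,
                confounder_effects=(1.5, 2000.0, -0.1))
            cohort, dosages, weights, _ = generate_cohort(p)
            prs = build_prs(dosages, weights)
            covs = cohort.covariate_matrix()
            y = cohort.df["annual_cost"].to_numpy()
            x = cohort.df["cancer"].to_numpy(float)
            iv = fit_2sls(y, x, prs, covs, outcome_label="annual_cost",
                          exposure_label="cancer")
            ols = fit_ols(y, x, covs, outcome_label="annual_cost",
                          exposure_label="cancer")
            rej += hausman_test(iv, ols).p_value < 0.05
        assert rej / 40 > 0.5

    def test_ols_bias_has_sign_of_injected_confounding(self):
        """OLS-2SLS discrepancy carries the confounder's sign (sign test
        over replicates)."""
        signs = []
        for s in range(30):
            p = GeneratorParams.realistic(
                10_000, seed=5_000 + s,
                confounder_effects=(1.0, 1500.0, -0.08))
            cohort, dosages, weights, _ = generate_cohort(p)
            prs = build_prs(dosages, weights)
            covs = cohort.covariate_matrix()
            y = cohort.df["annual_cost"].to_numpy()
            x = cohort.df["cancer"].to_numpy(float)
            diff = (fit_ols(y, x, covs).beta
                    - fit_2sls(y, x, prs, covs).beta)
            signs.append(diff > 0)
        # positive cost confounding biases OLS upward
        assert np.mean(signs) > 0.8


class TestStratified:
    def test_single_stratum_equals_unstratified(self, prostate_like):
        _, cohort, dosages, weights, _ = prostate_like
        cohort = cohort.copy()
        cohort.df["whole"] = "everyone"
        [sr] = stratified_mr(cohort, dosages, weights, StratumSpec("whole"))
        prs = build_prs(dosages, weights)
        direct = fit_2sls(cohort.df["annual_cost"].to_numpy(),
                          cohort.df["cancer"].to_numpy(float), prs,
                          cohort.covariate_matrix())
        assert sr.result.beta == pytest.approx(direct.beta, rel=1e-10)

    def test_sex_strata_drop_sex_covariate_and_fit(self, prostate_like):
        _, cohort, dosages, weights, _ = prostate_like
        results = stratified_mr(cohort, dosages, weights, StratumSpec("sex"))
        levels = {r.level for r in results}
        assert levels == {"male", "female"}
        assert all(r.result is not None for r in results)

    def test_caseless_stratum_reported_as_skipped(self):
        p = GeneratorParams.realistic(4_000, seed=6, sex_specific="male")
        cohort, dosages, weights, _ = generate_cohort(p)
        results = stratified_mr(cohort, dosages, weights, StratumSpec("sex"))
        by_level = {r.level: r for r in results}
        assert by_level["female"].skipped is not None
        assert by_level["male"].result is not None

    def test_age_bands_partition_cohort(self, small_cohort):
        _, cohort, dosages, weights, _ = small_cohort
        results = stratified_mr(cohort, dosages, weights,
                                StratumSpec("age_band"))
        n_total = sum(r.result.n for r in results if r.result is not None)
        assert n_total == len(cohort)

    def test_homogeneous_effects_show_no_between_stratum_heterogeneity(self):
        """Identical true effects in every age band: between-stratum Q is
        consistent with its chi-squared null."""
        from scipy import stats
        qs = []
        for s in range(20):
            p = GeneratorParams.realistic(15_000, seed=7_000 + s)
            cohort, dosages, weights, _ = generate_cohort(p)
            res = [r.result for r in
                   stratified_mr(cohort, dosages, weights,
                                 StratumSpec("age_band"))
                   if r.result is not None]
            b = np.array([r.beta for r in res])
            w = np.array([1 / r.se ** 2 for r in res])
            pooled = np.sum(w * b) / np.sum(w)
            qs.append(np.sum(w * (b - pooled) ** 2))
        pvals = stats.chi2.sf(qs, len(res) - 1)
        # under the null p-values are uniform; gross heterogeneity would
        # pile them near zero
        assert np.mean(pvals < 0.05) <= 0.25


class TestNegativeControl:
    def test_null_for_cross_sex_score(self):
        p = GeneratorParams.realistic(8_000, seed=31, sex_specific="male")
        cohort, dosages, weights, _ = generate_cohort(p)
        prs = build_prs(dosages, weights)
        res = negative_control(cohort, prs, "female")
        assert set(res) == {"annual_cost", "annual_qaly"}
        for r in res.values():
            assert abs(r.beta) <= 3 * r.se

    def test_own_sex_score_is_not_null(self):
        """Sanity inversion: in the sex that does express the cancer, a
        strong causal cost effect makes the PRS-outcome association
        clearly non-null."""
        p = GeneratorParams.realistic(20_000, seed=32, sex_specific="male",
                                      beta_cost=3000.0)
        cohort, dosages, weights, _ = generate_cohort(p)
        prs = build_prs(dosages, weights)
        res = negative_control(cohort, prs, "male")
        r = res["annual_cost"]
        assert abs(r.beta) > 2 * r.se

    def test_empty_control_sex_raises(self):
        p = GeneratorParams.realistic(2_000, seed=33)
        cohort, dosages, weights, _ = generate_cohort(p)
        women_only = cohort.subset(cohort.df["sex"].to_numpy() == "female")
        prs = build_prs(dosages, weights)
        with pytest.raises(ValueError, match="no male"):
            negative_control(women_only, np.asarray(prs)[
                cohort.df["sex"].to_numpy() == "female"], "male")


class TestImputeAndPool:
    @staticmethod
    def _fitter(cohort, prs, covs):
        cancer = cohort.df["cancer"].to_numpy(float)

        def fit(cost, _cohort):
            return fit_2sls(cost, cancer, prs.scores, covs,
                            outcome_label="annual_cost",
                            exposure_label="cancer")
        return fit

    def test_no_missing_data_returns_single_fit(self, small_cohort):
        _, cohort, dosages, weights, _ = small_cohort
        prs = build_prs(dosages, weights)
        covs = cohort.covariate_matrix()
        fit = self._fitter(cohort, prs, covs)
        pooled = impute_and_pool(cohort, 5, fit)
        single = fit(cohort.df["annual_cost"].to_numpy(), cohort)
        assert pooled.beta == single.beta and pooled.se == single.se

    def test_pooled_variance_at_least_within_variance(self):
        p = GeneratorParams.realistic(4_000, seed=41, missing_rate=0.5)
        cohort, dosages, weights, _ = generate_cohort(p)
        prs = build_prs(dosages, weights)
        covs = cohort.covariate_matrix()
        pooled = impute_and_pool(cohort, 10,
                                 self._fitter(cohort, prs, covs), seed=1)
        assert pooled.se ** 2 >= pooled.within_variance
        assert pooled.m == 10
        assert pooled.between_variance > 0

    def test_preconditions(self, small_cohort):
        _, cohort, dosages, weights, _ = small_cohort
        prs = build_prs(dosages, weights)
        covs = cohort.covariate_matrix()
        fit = self._fitter(cohort, prs, covs)
        with pytest.raises(ValueError, match="at least 2"):
            impute_and_pool(cohort, 1, fit)
        empty = cohort.copy()
        empty.df["annual_cost"] = np.nan
        with pytest.raises(ValueError, match="no observed costs"):
            impute_and_pool(empty, 5, fit)


def test_scale_qaly_is_times_100():
    assert scale_qaly(0.78) == pytest.approx(78.0)
    assert scale_qaly(0.0) == 0.0
    v = np.array([0.0, 0.5, 1.0])
    np.testing.assert_allclose(scale_qaly(v), v * 100.0)
    with pytest.raises(ValueError):
        scale_qaly(np.array([0.5, np.nan]))
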
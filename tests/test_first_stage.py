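"""First-stage fixed-effects regressions and residual (co)variances."""

import numpy as np
import pandas as pd
import pytest

from uvdemand import (
    EstimationError,
    PipelineConfig,
    SyntheticTruth,
    UnitValueRegression,
    fit_budget_share_eq,
    fit_first_stage,
    fit_unit_value_eq,
    generate,
    residual_covariances,
)
from uvdemand.design import LN_X, build_design
from uvdemand.first_stage import FirstStageFit, _group_codes, within_demean


@pytest.fixture(scope="module")
def noiseless_df():
    truth = SyntheticTruth(
        seed=17, n_clusters=25, households_per_cluster=8,
        participation_rate=1.0, alpha0=0.5 - 0.0066 * 8.12, share_floor=0.0,
        sigma11=0.0, sigma00=0.0, sigma10=0.0,
    )
    df, _ = generate(truth)
    return df, truth


@pytest.fixture(scope="module")
def five_cluster_df():
    """5 clusters x 4 households x 3 waves = 60 records, all consuming."""
    truth = SyntheticTruth(
        seed=23, n_clusters=5, households_per_cluster=4,
        participation_rate=1.0, alpha0=0.5 - 0.0066 * 8.12, share_floor=0.0,
        sigma00=0.001, sigma10=0.005, sigma11=0.09,
    )
    df, _ = generate(truth)
    assert len(df) == 60
    return df


class TestExactRecovery:
    def test_noiseless_beta1_recovered_to_1e8(self, noiseless_df):
        df, truth = noiseless_df
        fit = fit_unit_value_eq(df, PipelineConfig())
        assert fit.beta1_hat == pytest.approx(truth.beta1, abs=1e-8)
        assert fit.resid1.abs().max() < 1e-8

    def test_noiseless_beta0_recovered_to_1e8(self, noiseless_df):
        df, truth = noiseless_df
        fit = fit_budget_share_eq(df, PipelineConfig())
        assert fit.beta0_hat == pytest.approx(truth.beta0, abs=1e-8)

    def test_noiseless_gamma_recovered(self, noiseless_df):
        df, truth = noiseless_df
        fit = fit_unit_value_eq(df, PipelineConfig())
        # within-cluster-identified covariates recover exactly; the urban
        # indicator is cluster-level and absorbed
        assert fit.gamma1_hat["ln_hh_size"] == pytest.approx(-0.5774, abs=1e-8)
        assert "urban" not in fit.gamma1_hat.index


class TestDummyVariableOracle:
    def test_absorption_matches_explicit_dummy_ols(self, five_cluster_df):
        sm = pytest.importorskip("statsmodels.api")
        df = five_cluster_df
        fit = fit_unit_value_eq(df, PipelineConfig())

        y = np.log(df["unit_value"].to_numpy())
        X, names = build_design(df)
        keep = [i for i, nm in enumerate(names) if nm != "urban"]
        dummies = pd.get_dummies(df["cluster_id"]).to_numpy(float)
        Xd = np.column_stack([X[:, keep], dummies])
        res = sm.OLS(y, Xd).fit()
        oracle = dict(zip([names[i] for i in keep], res.params[:len(keep)]))

        assert fit.beta1_hat == pytest.approx(oracle[LN_X], abs=1e-8)
        for nm in ("ln_hh_size", "n_male", "head_female", "year_2017"):
            assert fit.gamma1_hat[nm] == pytest.approx(oracle[nm], abs=1e-8)

    def test_year_only_mode_matches_plain_ols(self, five_cluster_df):
        sm = pytest.importorskip("statsmodels.api")
        df = five_cluster_df
        fit = fit_unit_value_eq(df, PipelineConfig(fe_mode_eq1="year_only"))
        y = np.log(df["unit_value"].to_numpy())
        X, names = build_design(df)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        # LN_X is the first design column, i.e. params[1] after the constant
        assert fit.beta1_hat == pytest.approx(res.params[1], abs=1e-8)


class TestContracts:
    def test_budget_share_location_invariance(self, small_survey):
        df, _ = small_survey
        fit = fit_budget_share_eq(df, PipelineConfig())
        shifted = df.copy()
        shifted["budget_share"] = shifted["budget_share"] + 0.01
        fit2 = fit_budget_share_eq(shifted, PipelineConfig())
        assert fit2.beta0_hat == pytest.approx(fit.beta0_hat, abs=1e-10)

    def test_residuals_orthogonal_to_regressors(self, small_survey):
        df, _ = small_survey
        fit = fit_first_stage(df, PipelineConfig())
        cons = df.loc[fit.resid1.index]
        X, _ = build_design(cons)
        codes, n_g = _group_codes(cons["cluster_id"].to_numpy())
        Xd = within_demean(X, codes, n_g)
        dots = Xd.T @ fit.resid1.to_numpy()
        scale = np.sqrt((Xd**2).sum(axis=0)) * fit.resid1.std() + 1e-30
        assert np.max(np.abs(dots) / scale) < 1e-6

    def test_collinear_design_raises_naming_column(self, small_survey):
        df, _ = small_survey
        bad = df.copy()
        bad["max_educ_years"] = bad["head_educ_years"]
        with pytest.raises(EstimationError, match="ln_max_educ"):
            fit_unit_value_eq(bad, PipelineConfig())

    def test_too_few_clusters_rejected(self):
        truth = SyntheticTruth(seed=2, n_clusters=1, households_per_cluster=10)
        df, _ = generate(truth)
        with pytest.raises(EstimationError, match="clusters"):
            fit_unit_value_eq(df, PipelineConfig())

    def test_beta0_within_three_clustered_ses_of_truth(self, survey_df,
                                                       default_truth):
        fit = fit_budget_share_eq(survey_df, PipelineConfig())
        se = fit.se0[LN_X]
        assert abs(fit.beta0_hat - default_truth.beta0) < 3 * se

    def test_cluster_f_test_reported(self, survey_df):
        fit = fit_first_stage(survey_df, PipelineConfig())
        for key in ("unit_value", "budget_share"):
            f = fit.fe_f_tests[key]
            assert f["F"] > 1.0 and f["p"] < 0.05


class TestResidualCovariances:
    @staticmethod
    def _manual_fit(resid1, resid0, households, dof):
        fit = FirstStageFit()
        idx = pd.RangeIndex(len(resid1))
        fit.resid1 = pd.Series(resid1, index=idx, dtype=float)
        fit.resid0 = pd.Series(resid0, index=idx, dtype=float)
        fit.household1 = pd.Series(households, index=idx)
        fit.household0 = pd.Series(households, index=idx)
        fit.cluster1 = pd.Series(np.zeros(len(resid1), int), index=idx)
        fit.dof1 = fit.dof0 = dof
        fit._k1 = fit._k0 = 0
        fit._g1 = fit._g0 = 0
        return fit

    def test_identical_series_give_equal_moments(self):
        r = np.array([0.5, -0.2, 0.1, -0.4, 0.3, -0.3,
                      0.2, -0.1, 0.4, -0.5, 0.25, -0.25])
        hh = np.repeat(np.arange(4), 3)
        fit = self._manual_fit(r, r, hh, dof=12)
        s11, s00, s10 = residual_covariances(fit, PipelineConfig())
        assert s11 == pytest.approx(s00)
        assert s10 == pytest.approx(s11)

    def test_persistent_household_hand_example_clustered_vs_naive(self):
        # residuals perfectly persistent across the three waves of each
        # household: summing within household before forming products
        # triples the per-observation moment (sum_h (3*1)^2 = 9 per
        # household over 3 observations), so clustered/naive == 3 exactly
        r1 = np.tile([1.0, 1.0, 1.0, -1.0, -1.0, -1.0], 2)
        r0 = r1.copy()
        hh = np.repeat([0, 1, 2, 3], 3)
        fit = self._manual_fit(r1, r0, hh, dof=12)
        _, _, s10 = residual_covariances(fit, PipelineConfig())
        assert s10 == pytest.approx(3.0)
        fit2 = self._manual_fit(r1, r0, hh, dof=12)
        _, _, n10 = residual_covariances(
            fit2, PipelineConfig(temporal_clustering=False))
        assert n10 == pytest.approx(1.0)
        assert s10 / n10 == pytest.approx(3.0)

    def test_independent_errors_give_near_zero_sigma10(self,
                                                       all_consumer_truth):
        truth = all_consumer_truth.replace(
            sigma10=0.0, n_clusters=500, households_per_cluster=34,
            seed=37,
        )
        df, _ = generate(truth)
        assert len(df) == 51_000
        fit = fit_first_stage(df, PipelineConfig())
        n_h = fit.household1.nunique()
        # household-summed AR(1) products have variance ~ K^2 s11 s00 per
        # household with K = (3 + 4 rho + 2 rho^2)/3; 1.5 is a safe bound
        mc_se = 1.5 * np.sqrt(truth.sigma11 * truth.sigma00 / n_h)
        assert abs(fit.sigma10_hat) < 3 * mc_se

    def test_intersection_too_small_rejected(self):
        r = np.array([0.1, -0.1, 0.2, -0.2])
        hh = np.array([0, 0, 1, 1])
        fit = self._manual_fit(r, r, hh, dof=4)
        with pytest.raises(EstimationError, match="records"):
            residual_covariances(fit, PipelineConfig())

    def test_ar_errors_inflate_clustered_sigma11(self, survey_df,
                                                 default_truth):
        fit = fit_first_stage(survey_df, PipelineConfig())
        rho = default_truth.rho_time
        inflation = (3 + 4 * rho + 2 * rho**2) / 3
        target = default_truth.sigma11 * inflation
        assert fit.sigma11_hat == pytest.approx(target, rel=0.15)

        fit_naive = fit_first_stage(
            survey_df, PipelineConfig(temporal_clustering=False))
        assert fit_naive.sigma11_hat == pytest.approx(default_truth.sigma11,
                                                      rel=0.15)
        assert fit.sigma11_hat > fit_naive.sigma11_hat
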
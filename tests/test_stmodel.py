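"""Model specification and inference engine checks."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from reefbarrens import imagefilter, stmodel, synthetic
from reefbarrens.stmodel import (
    EngineConfig,
    Hyperparameters,
    PriorSpec,
    build_design_matrix,
    fit,
    fit_logistic_mcmc,
    log_marginal_likelihood,
    log_prior,
    phi_to_theta,
    spatial_correlation,
)


class TestSpatialCorrelation:
    def test_zero_distance(self):
        assert spatial_correlation(0.0, 10.0) == 1.0

    def test_range_definition(self):
        # at d = rho the correlation is "close to 0.1"
        h = spatial_correlation(17.055, 17.055)
        assert 0.05 <= h <= 0.15

    def test_strictly_decreasing(self):
        d = np.linspace(0.0, 80.0, 200)
        h = spatial_correlation(d, 17.0)
        assert np.all(np.diff(h) < 0)
        assert np.all((h > 0) & (h <= 1))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            spatial_correlation(1.0, -1.0)
        with pytest.raises(ValueError):
            spatial_correlation(-1.0, 1.0)


class TestDesignMatrix:
    def make_df(self, **overrides):
        base = {
            "barren": [0], "ntr": [0], "year_coded": [0.0],
            "rugosity_logit_std": [0.0], "depth_std": [0.0],
            "depth_sq_std": [0.0],
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_baseline_row(self):
        X, names = build_design_matrix(self.make_df())
        np.testing.assert_array_equal(X[0], [1, 0, 0, 0, 0, 0, 0])

    def test_interaction_column(self):
        X, _ = build_design_matrix(self.make_df(ntr=[1], year_coded=[5.0]))
        assert X[0, 1] == 1 and X[0, 2] == 5 and X[0, 6] == 5

    def test_reporting_order(self):
        _, names = build_design_matrix(self.make_df())
        assert names == ["intercept", "ntr", "year", "rugosity", "depth",
                         "depth_squared", "ntr_year"]

    def test_missing_column_named(self):
        df = self.make_df().drop(columns=["depth_std"])
        with pytest.raises(ValueError, match="depth_std"):
            build_design_matrix(df)


class TestLogPrior:
    def test_transformed_scale_modes(self):
        pr = PriorSpec()

        def transformed_density(rho=np.e**pr.a_rho, sigma=np.e**pr.a_sigma,
                                phi=0.0):
            # strip the Jacobians to recover the transformed-scale density
            lp = log_prior(Hyperparameters(rho, sigma**2, phi),
                           np.zeros(1), pr)
            return (lp + np.log(rho) + np.log(sigma)
                    - np.log(2 / (1 - phi**2)))

        centre = transformed_density()
        for eps in (-0.3, 0.3):
            assert transformed_density(rho=np.exp(pr.a_rho + eps)) < centre
            assert transformed_density(sigma=np.exp(pr.a_sigma + eps)) < centre
            assert transformed_density(
                phi=np.tanh((pr.a_phi + eps) / 2)) < centre

    def test_beta_contribution_closed_form(self):
        pr = PriorSpec()
        beta = np.zeros(7)
        lp0 = log_prior(Hyperparameters(20.0, 1.0, 0.0), beta, pr)
        lp1 = log_prior(Hyperparameters(20.0, 1.0, 0.0), beta[:0], pr)
        want = 7 * norm.logpdf(0.0, 0.0, pr.s_beta)
        assert lp0 - lp1 == pytest.approx(want, abs=1e-12)

    def test_phi_transform_identity(self):
        assert phi_to_theta(0.0) == 0.0
        assert stmodel.theta_to_phi(phi_to_theta(0.6)) == pytest.approx(0.6)

    def test_phi_out_of_range(self):
        with pytest.raises(ValueError):
            Hyperparameters(10.0, 1.0, 1.0)


def _simulate_m1_table(small_table, beta, rng):
    """Redraw the outcome from a fixed-effects-only truth on fixed X."""
    df = small_table.df.copy()
    X, _ = build_design_matrix(df)
    p = expit(X @ np.asarray(beta))
    df["barren"] = (rng.random(len(df)) < p).astype(int)
    return df


BETA_TRUTH = np.array([-1.0, -0.8, 0.25, 0.5, -0.3, -0.7, 0.1])


class TestM1:
    def test_matches_reference_mle_with_wide_prior(self, small_table):
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        df = _simulate_m1_table(small_table, BETA_TRUTH, rng)
        X, _ = build_design_matrix(df)
        y = df["barren"].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = fit_logistic_mcmc(X, y, priors=PriorSpec(s_beta=50.0),
                                  engine=EngineConfig(seed=3))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            f.fixed_effect_summary["mean"], ref.params, atol=0.15
        )
        np.testing.assert_allclose(
            f.fixed_effect_summary["sd"], ref.bse, rtol=0.25
        )

    def test_posterior_sd_shrinks_with_prior(self, small_table):
        rng = np.random.default_rng(29)
        df = _simulate_m1_table(small_table, BETA_TRUTH, rng)
        sds = []
        for s_beta in (10.0, 1.0, 0.1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = fit(df, "M1", priors=PriorSpec(s_beta=s_beta),
                        engine_config=EngineConfig(seed=5))
            sds.append(f.fixed_effect_summary["sd"].to_numpy())
        # elementwise shrinkage up to Monte-Carlo slack on well-identified
        # coefficients, strict on average
        assert np.all(sds[1] <= sds[0] * 1.05) and np.all(sds[2] <= sds[1] * 1.05)
        assert sds[1].mean() < sds[0].mean() and sds[2].mean() < sds[1].mean()

    def test_draw_quantiles_match_summary(self, m1_fit):
        draws = m1_fit.draws[stmodel.FIXED_EFFECT_NAMES].to_numpy()
        q = np.percentile(draws, 50, axis=0)
        np.testing.assert_allclose(
            q, m1_fit.fixed_effect_summary["q0.5"], atol=1e-9
        )
        s = m1_fit.fixed_effect_summary
        assert (s["q0.025"] < s["q0.5"]).all() and (s["q0.5"] < s["q0.975"]).all()

    def test_degenerate_outcome_rejected(self, small_table):
        df = small_table.df.copy()
        df["barren"] = 0
        with pytest.raises(ValueError, match="all 0 or all 1"):
            fit(df, "M1")

    def test_at_least_5000_draws(self, m1_fit):
        assert len(m1_fit.draws) >= 5000


class TestEvidence:
    def test_duplicated_data_evidence_sanity(self, small_table):
        # the likelihood multiplies but the prior integrates once: for a
        # stacked copy of the data, Jensen gives logML2 >= 2 logML1, while
        # every Bernoulli likelihood factor <= 1 gives logML2 <= logML1
        rng = np.random.default_rng(41)
        df = _simulate_m1_table(small_table, BETA_TRUTH, rng).iloc[:120]
        df2 = pd.concat([df, df], ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit(df, "M1", engine_config=EngineConfig(seed=7))
            f2 = fit(df2, "M1", engine_config=EngineConfig(seed=7))
        slack = 3 * (f1.log_ml_se + f2.log_ml_se)
        assert f2.log_marginal_likelihood >= 2 * f1.log_marginal_likelihood - slack
        assert f2.log_marginal_likelihood <= f1.log_marginal_likelihood + slack

    def test_refuses_nonconverged_fit(self, m1_fit):
        import dataclasses

        bad = dataclasses.replace(
            m1_fit, diagnostics={**m1_fit.diagnostics, "converged": False}
        )
        with pytest.raises(RuntimeError, match="non-converged"):
            log_marginal_likelihood(bad)
        assert np.isfinite(log_marginal_likelihood(m1_fit))


class TestNestedModels:
    @pytest.fixture(scope="class")
    def sigma_zero_fits(self, small_table):
        rng = np.random.default_rng(53)
        df = _simulate_m1_table(small_table, BETA_TRUTH, rng)
        eng = EngineConfig.fast(seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit(df, "M1", engine_config=EngineConfig(seed=9))
            f3 = fit(df, "M3", engine_config=eng)
        return f1, f3

    def test_m3_on_independent_data_shrinks_spatial_sd(self, sigma_zero_fits):
        _, f3 = sigma_zero_fits
        # data carry no spatial signal: posterior spatial sd concentrates
        # well below the prior median exp(a_sigma) = 1
        assert f3.hyper_summary.loc["spatial_sd", "q0.5"] < 1.0

    def test_m3_beta_matches_m1_in_the_limit(self, sigma_zero_fits):
        f1, f3 = sigma_zero_fits
        m1 = f1.fixed_effect_summary["mean"].to_numpy()
        m3 = f3.fixed_effect_summary["mean"].to_numpy()
        np.testing.assert_allclose(m3, m1, atol=0.35)

    def test_m2_has_no_temporal_parameter(self, small_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f2 = fit(small_table, "M2", engine_config=EngineConfig.fast(seed=13))
        assert "temporal_correlation" not in f2.hyper_summary.index
        assert {"range_m", "spatial_sd"} <= set(f2.hyper_summary.index)

    def test_unknown_model_rejected(self, small_table):
        with pytest.raises(ValueError, match="model_id"):
            fit(small_table, "M7")
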
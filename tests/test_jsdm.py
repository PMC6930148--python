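import numpy as np
import pandas as pd
import pytest

from succnet import jsdm
from succnet.jsdm import (JsdmModel, JsdmPosterior, env_variance_explained,
                          fit_jsdm, forward_select_env, geweke_diagnostic,
                          quantile_residuals, residual_correlation_draws,
                          significant_edges, spherical_correlation,
                          summarize_residual_correlations)


class TestSphericalCorrelation:
    def test_zero_distance_is_one(self):
        assert spherical_correlation(0.0, 10.0) == 1.0

    def test_beyond_range_is_zero(self):
        assert spherical_correlation(10.0, 10.0) == 0.0
        assert spherical_correlation(25.0, 10.0) == 0.0

    def test_half_range_cubic(self):
        # 1 - 1.5*0.5 + 0.5*0.125 = 0.3125
        assert spherical_correlation(5.0, 10.0) == pytest.approx(0.3125)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            spherical_correlation(1.0, 0.0)

    def test_monotone_decreasing(self):
        h = np.linspace(0, 12, 50)
        v = spherical_correlation(h, 10.0)
        assert (np.diff(v) <= 1e-12).all()


class TestForwardSelection:
    def test_signal_covariate_selected_first(self):
        rng = np.random.default_rng(0)
        n, p = 60, 8
        a = rng.normal(size=n)
        y = np.outer(a, rng.normal(size=p)) + 0.3 * rng.normal(size=(n, p))
        cands = pd.DataFrame({"noise1": rng.normal(size=n), "signal": a,
                              "noise2": rng.normal(size=n)})
        assert forward_select_env(y, cands, 2)[0] == "signal"

    def test_k_zero_empty(self):
        y = np.zeros((5, 2))
        cands = pd.DataFrame({"a": np.arange(5.0)})
        assert forward_select_env(y, cands, 0) == []

    def test_duplicated_covariate_skipped(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        y = np.outer(a, rng.normal(size=4)) + 0.1 * rng.normal(size=(40, 4))
        cands = pd.DataFrame({"a": a, "a_copy": a.copy(),
                              "b": rng.normal(size=40)})
        sel = forward_select_env(y, cands, 2)
        assert "a" in sel and "a_copy" not in sel

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            forward_select_env(np.zeros((4, 2)),
                               pd.DataFrame({"a": np.arange(4.0)}), 2)


class TestFitJsdm:
    def test_retained_draw_count_small_schedule(self):
        rng = np.random.default_rng(2)
        m = JsdmModel(y=rng.normal(size=(12, 3)), x=None, coords=None, d=0)
        post = fit_jsdm(m, iterations=400, burn_in=100, thin=3, seed=0)
        assert post.n_draws == 100

    def test_burn_in_must_be_smaller(self):
        m = JsdmModel(y=np.zeros((5, 2)) + np.eye(5, 2), x=None, coords=None, d=0)
        with pytest.raises(ValueError):
            fit_jsdm(m, iterations=100, burn_in=100, thin=1, seed=0)

    def test_environment_only_matches_least_squares(self):
        # with vague priors the d=0 posterior mean is the per-taxon OLS fit
        rng = np.random.default_rng(3)
        n, p, q = 100, 5, 2
        x = rng.normal(size=(n, q))
        y = 0.5 + x @ rng.normal(size=(q, p)) + 0.8 * rng.normal(size=(n, p))
        m = JsdmModel(y=y, x=x, coords=None, d=0)
        post = fit_jsdm(m, 3000, 500, 2, seed=4)
        g = np.column_stack([np.ones(n), jsdm.zscore_columns(x)])
        ols = np.linalg.lstsq(g, y, rcond=None)[0]
        pm = np.vstack([post.beta0.mean(0)[None, :], post.beta.mean(0)])
        sd = np.vstack([post.beta0.std(0)[None, :], post.beta.std(0)])
        mc_se = sd / np.sqrt(post.n_draws / 20)  # conservative ESS guess
        assert (np.abs(pm - ols) < 2 * mc_se).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(15, 6))
        coords = rng.uniform(0, 100, size=(15, 2))
        m = JsdmModel(y=y, x=None, coords=coords, d=2)
        p1 = fit_jsdm(m, 300, 100, 2, seed=9)
        p2 = fit_jsdm(m, 300, 100, 2, seed=9)
        np.testing.assert_array_equal(p1.loadings, p2.loadings)
        np.testing.assert_array_equal(p1.phi, p2.phi)

    def test_near_zero_response_concentrates_near_zero(self):
        rng = np.random.default_rng(6)
        y = 1e-3 * rng.normal(size=(30, 4))
        m = JsdmModel(y=y, x=rng.normal(size=(30, 1)), coords=None, d=1)
        post = fit_jsdm(m, 800, 300, 2, seed=1)
        assert np.abs(post.beta.mean(0)).max() < 0.05
        assert np.abs(post.loadings.mean(0)).max() < 0.05

    def test_identifiability_constraint_holds(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(20, 6))
        coords = rng.uniform(0, 50, size=(20, 2))
        m = JsdmModel(y=y, x=None, coords=coords, d=3)
        post = fit_jsdm(m, 400, 100, 3, seed=2)
        lam = post.loadings
        assert (lam[:, 0, 1:] == 0).all() and (lam[:, 1, 2:] == 0).all()
        assert (lam[:, np.arange(3), np.arange(3)] > 0).all()
        assert (post.phi >= 0).all()


def _posterior_from_loadings(lams, sigma2s):
    """Hand-built posterior with given per-draw loadings for analytic checks."""
    lams = np.asarray(lams, dtype=float)
    sigma2s = np.asarray(sigma2s, dtype=float)
    m, p, d = lams.shape
    return JsdmPosterior(
        beta0=np.zeros((m, p)), beta=np.zeros((m, 0, p)), loadings=lams,
        scores=np.zeros((m, 4, d)), sigma2=sigma2s, phi=np.full(m, np.nan),
        taxon_ids=[f"t{j}" for j in range(p)])


class TestResidualCorrelations:
    def test_zero_loadings_identity(self):
        post = _posterior_from_loadings(np.zeros((3, 4, 2)), np.ones((3, 4)))
        rho = residual_correlation_draws(post)
        for t in range(3):
            np.testing.assert_allclose(rho[t], np.eye(4))

    def test_shared_axis_zero_noise_full_correlation(self):
        lam = np.zeros((1, 3, 3))
        lam[0, 0] = [1, 0, 0]
        lam[0, 1] = [1, 0, 0]
        lam[0, 2] = [0, 1, 0]
        post = _posterior_from_loadings(lam, np.full((1, 3), 1e-12))
        rho = residual_correlation_draws(post)[0]
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(0.0, abs=1e-6)

    def test_draws_are_symmetric_psd_unit_diagonal(self):
        rng = np.random.default_rng(8)
        post = _posterior_from_loadings(rng.normal(size=(5, 6, 2)),
                                        rng.uniform(0.5, 2.0, size=(5, 6)))
        rho = residual_correlation_draws(post)
        for t in range(5):
            np.testing.assert_allclose(rho[t], rho[t].T)
            np.testing.assert_allclose(np.diag(rho[t]), 1.0)
            assert np.linalg.eigvalsh(rho[t]).min() > -1e-10

    def test_d_zero_rejected(self):
        post = _posterior_from_loadings(np.zeros((2, 3, 0)), np.ones((2, 3)))
        with pytest.raises(ValueError):
            residual_correlation_draws(post)

    def test_summary_interval_ordering(self):
        rng = np.random.default_rng(9)
        post = _posterior_from_loadings(rng.normal(size=(40, 5, 2)),
                                        rng.uniform(0.5, 2.0, size=(40, 5)))
        rho = residual_correlation_draws(post)
        s = summarize_residual_correlations(rho, post.taxon_ids, 0.95)
        assert (s.lower <= s.median).all() and (s.median <= s.upper).all()
        assert s.lower.min() >= -1 and s.upper.max() <= 1


class TestSignificantEdges:
    def _summary(self, lower, median, upper, p=3):
        """Three-taxon summary where only the (t0, t1) pair is specified;
        every other pair's interval straddles zero."""
        from succnet.jsdm import ResidualCorrelationSummary
        low = np.full((p, p), -0.5)
        med = np.zeros((p, p))
        up = np.full((p, p), 0.5)
        low[0, 1] = low[1, 0] = lower
        med[0, 1] = med[1, 0] = median
        up[0, 1] = up[1, 0] = upper
        return ResidualCorrelationSummary([f"t{j}" for j in range(p)],
                                          med, low, up, 0.95)

    def test_interval_straddling_zero_no_edge(self):
        e = significant_edges(self._summary(-0.1, 0.05, 0.2))
        assert len(e) == 0

    def test_positive_interval_positive_edge(self):
        e = significant_edges(self._summary(0.05, 0.2, 0.4))
        row = e[(e.taxon_a == "t0") & (e.taxon_b == "t1")].iloc[0]
        assert row["sign"] == "positive" and row["median_rho"] == 0.2

    def test_negative_interval_negative_edge(self):
        e = significant_edges(self._summary(-0.6, -0.3, -0.05))
        row = e[(e.taxon_a == "t0") & (e.taxon_b == "t1")].iloc[0]
        assert row["sign"] == "negative"


class TestEnvVarianceExplained:
    def test_exact_linear_response_r2_one(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(50, 2))
        y = x @ rng.normal(size=(2, 4))
        m = JsdmModel(y=y, x=x, coords=None, d=0)
        post = fit_jsdm(m, 1500, 500, 2, seed=3)
        r2, mean_r2 = env_variance_explained(m, post)
        assert mean_r2 > 0.999

    def test_independent_covariates_near_zero(self):
        # Pure-noise covariates: the least-squares projection absorbs
        # ~q/(n-1) of the variance, but averaging the residual SS over the
        # posterior adds back the parameter-uncertainty term (~(q+1)/n), so
        # the posterior-expected R^2 sits near zero under the null rather
        # than at the in-sample optimism level. It must not be meaningfully
        # positive.
        rng = np.random.default_rng(11)
        n, q = 40, 3
        means = []
        for rep in range(10):
            x = rng.normal(size=(n, q))
            y = rng.normal(size=(n, 6))
            m = JsdmModel(y=y, x=x, coords=None, d=0)
            post = fit_jsdm(m, 600, 200, 2, seed=rep)
            means.append(env_variance_explained(m, post)[1])
        assert -0.09 < np.mean(means) < 0.03

    def test_requires_environment_only_fit(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(15, 3))
        m = JsdmModel(y=y, x=rng.normal(size=(15, 1)), coords=None, d=1)
        post = fit_jsdm(m, 200, 100, 1, seed=0)
        with pytest.raises(ValueError):
            env_variance_explained(m, post)


class TestGeweke:
    def test_iid_chain_rarely_flags(self):
        rng = np.random.default_rng(13)
        zs = [geweke_diagnostic(rng.normal(size=1000)) for _ in range(500)]
        assert np.mean(np.abs(zs) < 3) >= 0.99

    def test_mean_shift_flags(self):
        chain = np.concatenate([np.zeros(500), np.full(500, 3.0)])
        chain += np.random.default_rng(14).normal(0, 0.1, size=1000)
        assert abs(geweke_diagnostic(chain)) > 5

    def test_constant_chain_missing(self):
        assert np.isnan(geweke_diagnostic(np.ones(100)))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            geweke_diagnostic(np.arange(10.0))


class TestQuantileResiduals:
    def test_well_specified_model_standard_normal(self):
        rng = np.random.default_rng(15)
        n, p = 60, 5
        x = rng.normal(size=(n, 2))
        y = 1.0 + x @ rng.normal(size=(2, p)) + rng.normal(size=(n, p))
        m = JsdmModel(y=y, x=x, coords=None, d=0)
        post = fit_jsdm(m, 1500, 500, 2, seed=5)
        resid, qq = quantile_residuals(m, post)
        assert resid.mean() == pytest.approx(0.0, abs=0.05)
        assert resid.std() == pytest.approx(1.0, abs=0.07)
        assert qq["qq_slope"] == pytest.approx(1.0, abs=0.1)

    def test_heavy_tails_detected_in_qq_diagnostics(self):
        # Contaminated data inflate the Gaussian scale estimate, so the QQ
        # line pulls away from unit slope while the residual distribution
        # turns leptokurtic; both deviations flag the misspecification.
        rng = np.random.default_rng(16)
        n, p = 200, 5
        y = rng.normal(size=(n, p))
        out = y.copy()
        out[::7] += rng.normal(0, 6, size=out[::7].shape)  # contamination
        m_clean = JsdmModel(y=y, x=None, coords=None, d=0)
        m_out = JsdmModel(y=out, x=None, coords=None, d=0)
        r_clean, qq_clean = quantile_residuals(
            m_clean, fit_jsdm(m_clean, 600, 200, 2, seed=6))
        r_out, qq_out = quantile_residuals(
            m_out, fit_jsdm(m_out, 600, 200, 2, seed=6))
        kurt = lambda r: float(((r - r.mean())**4).mean() / r.var()**2)
        assert abs(qq_clean["qq_slope"] - 1) < 0.05
        assert abs(qq_out["qq_slope"] - 1) > 0.05
        assert kurt(r_out) > kurt(r_clean) + 1.0
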
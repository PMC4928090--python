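"""NB-GLM engine: closed forms, independent oracles, calibration."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

from xdiverge.nbglm import (
    adjusted_profile_loglik,
    estimate_dispersion,
    fit_nb_glm,
    lrt_contrast,
    nb_deviance,
    nb_loglik,
)

from conftest import nb_draws, two_group_design


class TestFit:
    def test_intercept_only_recovers_the_mean_with_zero_deviance_at_equal_counts(self):
        y = np.full(5, 7.0)
        fit = fit_nb_glm(y, np.ones((5, 1)), dispersion=0.1)
        assert np.isclose(fit.mu[0, 0], 7.0, atol=1e-6)
        assert abs(fit.deviance[0]) < 1e-8

    def test_intercept_only_deviance_matches_closed_form(self):
        y = np.array([3.0, 9.0, 6.0, 6.0])
        phi = 0.2
        fit = fit_nb_glm(y, np.ones((4, 1)), dispersion=phi)
        assert np.isclose(fit.mu[0, 0], y.mean(), atol=1e-4)
        expected = nb_deviance(y, np.full(4, y.mean()), phi)
        assert np.isclose(fit.deviance[0], expected, atol=1e-6)

    def test_two_group_poisson_limit_gives_log_ratio_coefficient(self):
        y = np.array([10.0, 10, 10, 40, 40, 40])
        fit = fit_nb_glm(y, two_group_design(), dispersion=0.0)
        assert np.isclose(fit.beta[0, 1], np.log(4.0), atol=1e-8)

    def test_irls_matches_direct_likelihood_maximization(self):
        """IRLS beta-hat vs scipy minimization of the exact NB likelihood."""
        rng = np.random.default_rng(5)
        X = two_group_design()
        phi = 0.2
        y = nb_draws(rng, np.array([80, 80, 80, 200, 200, 200.0]), phi).astype(float)
        fit = fit_nb_glm(y, X, dispersion=phi)

        def nll(beta):
            mu = np.exp(X @ beta)
            return -nb_loglik(y, mu, phi).sum()

        res = minimize(nll, x0=[4.0, 0.5], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert np.allclose(fit.beta[0], res.x, atol=1e-3)

    def test_irls_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        X = two_group_design(4)
        phi = 0.1
        y = nb_draws(rng, np.full(8, 150.0), phi).astype(float)
        offs = np.linspace(-0.2, 0.2, 8)
        fit = fit_nb_glm(y, X, offsets=offs, dispersion=phi)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=phi),
                     offset=offs).fit()
        assert np.allclose(fit.beta[0], ref.params, atol=1e-5)

    def test_deviance_never_negative_and_converged_flags_set(self):
        rng = np.random.default_rng(2)
        y = nb_draws(rng, np.full((50, 6), 100.0), 0.1).astype(float)
        fit = fit_nb_glm(y, two_group_design(), dispersion=0.1)
        assert np.all(fit.deviance >= 0)
        assert np.all(fit.converged)

    def test_poisson_limit_deviance_matches_poisson_deviance(self):
        y = np.array([4.0, 0.0, 9.0, 2.0])
        mu = np.array([3.0, 1.0, 8.0, 2.5])
        pois = 2 * np.sum(
            np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0) - (y - mu)
        )
        for phi in (0.0, 1e-9):
            assert np.isclose(nb_deviance(y, mu, phi), pois, atol=1e-6)

    def test_all_zero_gene_is_flagged_and_excluded_from_testing(self):
        y = np.vstack([np.zeros(6), np.full(6, 20.0)])
        fit = fit_nb_glm(y, two_group_design(), dispersion=0.05)
        assert not fit.ok[0] and fit.ok[1]
        _, p = lrt_contrast(fit, np.array([0.0, 1.0]))
        assert np.isnan(p[0]) and not np.isnan(p[1])

    def test_nonfinite_counts_rejected(self):
        y = np.array([1.0, np.nan, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="finite"):
            fit_nb_glm(y, two_group_design(), dispersion=0.1)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="full rank"):
            fit_nb_glm(np.arange(6.0), X, dispersion=0.1)


class TestDeviancePath:
    def test_likelihood_is_monotone_over_irls_iterations(self, monkeypatch):
        """Step-halving guarantees the deviance never increases.

        Refit with an increasing iteration cap and check the per-gene
        deviance sequence is non-increasing in the cap.
        """
        from xdiverge import nbglm

        rng = np.random.default_rng(12)
        X = two_group_design()
        y = nb_draws(rng, np.full((20, 6), 60.0), 0.3).astype(float)
        phi = np.full(20, 0.3)
        traces = []
        for cap in range(1, 12):
            monkeypatch.setattr(nbglm, "_MAX_ITER", cap)
            _, _, dev, _ = nbglm._irls(y, X, np.zeros(6), phi)
            traces.append(dev)
        traces = np.array(traces)
        assert np.all(np.diff(traces, axis=0) <= 1e-9)


class TestDispersion:
    def test_poisson_counts_give_near_zero_common_dispersion(self):
        rng = np.random.default_rng(21)
        mu = rng.lognormal(np.log(200), 1.0, size=(2000, 1)) * np.ones(6)
        y = rng.poisson(mu)
        phi = estimate_dispersion(y, two_group_design())
        assert phi < 0.05

    def test_common_dispersion_recovers_truth(self):
        rng = np.random.default_rng(22)
        mu = rng.lognormal(np.log(200), 1.0, size=(2000, 1)) * np.ones(6)
        y = nb_draws(rng, mu, 0.1)
        phi = estimate_dispersion(y, two_group_design())
        assert 0.07 <= phi <= 0.13

    def test_single_gene_common_equals_grid_search_of_its_apl(self):
        rng = np.random.default_rng(23)
        X = two_group_design()
        y = nb_draws(rng, np.full(6, 120.0), 0.15).astype(float)
        phi = estimate_dispersion(y, X)
        grid = np.exp(np.linspace(np.log(1e-4), np.log(2.0), 4000))
        apl = np.array([adjusted_profile_loglik(p, y, X)[0] for p in grid])
        best = grid[np.argmax(apl)]
        assert abs(phi - best) < 1e-3

    def test_tagwise_shrinks_toward_common(self):
        rng = np.random.default_rng(24)
        X = two_group_design()
        mu = rng.lognormal(np.log(150), 0.8, size=(200, 1)) * np.ones(6)
        y = nb_draws(rng, mu, 0.1)
        common = estimate_dispersion(y, X, method="common")
        strong = estimate_dispersion(y, X, method="tagwise", prior_df=1000.0)
        weak = estimate_dispersion(y, X, method="tagwise", prior_df=1.0)
        # a huge prior pins every gene near the common value
        assert np.all(np.abs(np.log(strong / common)) < np.abs(np.log(weak / common)) + 0.2)
        assert np.median(np.abs(np.log(strong / common))) < 0.05

    def test_design_without_residual_df_rejected(self):
        X = np.eye(4)
        with pytest.raises(ValueError, match="residual"):
            estimate_dispersion(np.ones((3, 4)), X)


class TestLRT:
    def test_no_signal_gives_zero_statistic_and_p_near_one(self):
        y = np.full(6, 25.0)
        fit = fit_nb_glm(y, two_group_design(), dispersion=0.1)
        stat, p = lrt_contrast(fit, np.array([0.0, 1.0]))
        assert stat[0] < 1e-8
        assert p[0] > 0.999

    def test_type_one_error_is_calibrated_under_the_null(self):
        """Empirical rejection at alpha=0.05 for 1000 true-null genes."""
        rng = np.random.default_rng(11)
        X = two_group_design()
        mu = rng.lognormal(np.log(200), 1.0, size=(1000, 1)) * np.ones(6)
        y = nb_draws(rng, mu, 0.1)
        phi = estimate_dispersion(y, X)
        fit = fit_nb_glm(y, X, dispersion=phi)
        _, p = lrt_contrast(fit, np.array([0.0, 1.0]))
        rate = np.mean(p < 0.05)
        assert 0.03 <= rate <= 0.07

    def test_power_for_planted_eightfold_change(self):
        """|log2 fc| = 3 at n=3 vs 3, mu=100, phi=0.05: p < 0.001 almost always."""
        rng = np.random.default_rng(13)
        X = two_group_design()
        y = np.hstack([
            nb_draws(rng, np.full((500, 3), 100.0), 0.05),
            nb_draws(rng, np.full((500, 3), 800.0), 0.05),
        ]).astype(float)
        fit = fit_nb_glm(y, X, dispersion=0.05)
        _, p = lrt_contrast(fit, np.array([0.0, 1.0]))
        assert np.mean(p < 0.001) >= 0.95

    def test_statistic_is_chi2_distributed_under_null(self):
        rng = np.random.default_rng(14)
        X = two_group_design()
        mu = np.full((2000, 1), 300.0) * np.ones(6)
        y = nb_draws(rng, mu, 0.05)
        fit = fit_nb_glm(y, X, dispersion=0.05)
        stat, _ = lrt_contrast(fit, np.array([0.0, 1.0]))
        # compare upper quantiles against chi2(1)
        assert abs(np.quantile(stat, 0.95) - chi2.ppf(0.95, 1)) < 0.6

    def test_bad_contrasts_rejected(self):
        y = np.arange(1.0, 7.0)
        fit = fit_nb_glm(y, two_group_design(), dispersion=0.1)
        with pytest.raises(ValueError, match="length"):
            lrt_contrast(fit, np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="nonzero"):
            lrt_contrast(fit, np.zeros(2))
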
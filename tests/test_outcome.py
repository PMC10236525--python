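"""Outcome linear mixed model: densities, conjugate updates, ICC."""

import numpy as np
import pytest

from crtsace.outcome import (
    OutcomeParams,
    Priors,
    gibbs_update_cluster_effects,
    gibbs_update_coefficients,
    gibbs_update_variances,
    outcome_icc,
    outcome_log_density,
)
from crtsace.strata import G_ALWAYS, G_NEVER, G_PROTECTED

from conftest import make_dataset


def make_params(p=2, n_clusters=4, sigma2=1.0, tau2=1.0):
    zero = np.zeros(p)
    return OutcomeParams(
        alpha_11_1=zero.copy(),
        alpha_11_0=zero.copy(),
        alpha_10_1=zero.copy(),
        eta=np.zeros(n_clusters),
        sigma2=sigma2,
        tau2=tau2,
    )


class TestLogDensity:
    def test_zero_residual_is_the_normalizing_constant(self):
        params = make_params(p=3, sigma2=2.5)
        params.alpha_11_1 = np.array([1.5, 0.5, 0.8])
        params.eta[1] = 0.1
        x = np.array([1.0, 1.0, 0.0])
        y = float(x @ params.alpha_11_1) + 0.1
        ld = outcome_log_density(y, x, arm=1, stratum=G_ALWAYS, params=params, cluster_index=1)
        assert ld == pytest.approx(-0.5 * np.log(2 * np.pi * 2.5))

    def test_unit_normal_at_one(self):
        params = make_params()
        ld = outcome_log_density(1.0, np.array([1.0, 0.0]), 0, G_ALWAYS, params, 0)
        assert ld == pytest.approx(-0.5 * np.log(2 * np.pi) - 0.5)

    def test_protected_treated_cell(self):
        params = make_params(p=3, sigma2=5.0)
        params.alpha_10_1 = np.array([1.5, 0.5, 0.8])
        params.eta[0] = 0.1
        resid = 2.0 - 2.1
        expected = -0.5 * np.log(2 * np.pi * 5.0) - 0.5 * resid**2 / 5.0
        ld = outcome_log_density(
            2.0, np.array([1.0, 1.0, 0.0]), 1, G_PROTECTED, params, 0
        )
        assert ld == pytest.approx(expected)

    def test_unmodeled_cells_raise(self):
        params = make_params()
        with pytest.raises(ValueError, match="no outcome model"):
            outcome_log_density(0.0, np.array([1.0, 0.0]), 1, G_NEVER, params, 0)
        with pytest.raises(ValueError, match="no outcome model"):
            outcome_log_density(0.0, np.array([1.0, 0.0]), 0, G_PROTECTED, params, 0)


class TestGibbsCoefficients:
    def test_empty_cell_draws_from_the_prior(self, rng):
        ds = make_dataset(treated=[0, 0, 0, 0])  # no treated rows at all
        G = np.full(ds.n, G_ALWAYS)
        priors = Priors(coef_prior_var=4.0)
        draws = []
        params = make_params()
        for _ in range(3000):
            params = gibbs_update_coefficients(ds, G, params, priors, rng)
            draws.append(params.alpha_11_1.copy())  # treated cell is empty
        draws = np.array(draws)
        assert abs(draws.mean()) < 0.15
        assert np.allclose(draws.std(axis=0), 2.0, atol=0.15)

    def test_conditional_matches_closed_form_ridge(self, rng):
        """5-row fixture: Gibbs mean/cov equal the dense ridge solution."""
        ds = make_dataset(n_clusters=1, size=5, treated=[0], seed=3)
        G = np.full(ds.n, G_ALWAYS)
        priors = Priors(coef_prior_var=10.0)
        params = make_params(n_clusters=1, sigma2=2.0)
        eta = 0.3
        params.eta[:] = eta

        prec = ds.X.T @ ds.X / 2.0 + np.eye(2) / 10.0
        mean = np.linalg.solve(prec, ds.X.T @ (ds.Y - eta) / 2.0)
        cov = np.linalg.inv(prec)

        draws = []
        for _ in range(6000):
            params.eta[:] = eta
            params.sigma2 = 2.0
            params = gibbs_update_coefficients(ds, G, params, priors, rng)
            draws.append(params.alpha_11_0.copy())  # control always-survivors
        draws = np.array(draws)
        se = np.sqrt(np.diag(cov) / len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se)
        assert np.allclose(np.cov(draws.T), cov, rtol=0.12, atol=0.005)


class TestGibbsClusterEffects:
    def test_empty_cluster_draws_from_prior(self, rng):
        ds = make_dataset(n_clusters=3, size=4, treated=[1, 1, 0], seed=5)
        # mark every row of cluster 0 as never-survivor: no outcome rows
        G = np.full(ds.n, G_ALWAYS)
        G[ds.cluster == 0] = G_NEVER
        params = make_params(n_clusters=3, tau2=2.0)
        draws = np.array(
            [
                gibbs_update_cluster_effects(ds, G, params, rng).eta[0]
                for _ in range(4000)
            ]
        )
        assert abs(draws.mean()) < 0.1
        assert draws.std() == pytest.approx(np.sqrt(2.0), abs=0.08)

    def test_posterior_moments_match_the_stated_formula(self, rng):
        # one cluster, 4 observed rows, residual sum 2, sigma2=2, tau2=1
        ds = make_dataset(n_clusters=1, size=4, treated=[0], seed=1)
        ds.Y[:] = 0.5  # alphas are zero, so residuals are the outcomes
        G = np.full(ds.n, G_ALWAYS)
        params = make_params(n_clusters=1, sigma2=2.0, tau2=1.0)
        params.alpha_11_0[:] = 0.0
        draws = []
        for _ in range(6000):
            params = gibbs_update_cluster_effects(ds, G, params, rng)
            draws.append(params.eta[0])
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(1 / 3, abs=4 * np.sqrt(1 / 3 / len(draws)))
        assert draws.var() == pytest.approx(1 / 3, rel=0.1)


class TestGibbsVariances:
    def test_residuals_set_the_inverse_gamma_rate(self, rng):
        # two observed rows with residuals (1, -1): shape 1.01, rate 1.01
        ds = make_dataset(n_clusters=1, size=2, treated=[0], seed=2)
        ds.Y[:] = [1.0, -1.0]
        G = np.full(ds.n, G_ALWAYS)
        priors = Priors()
        params = make_params(n_clusters=1)
        inv_draws = []
        for _ in range(6000):
            params.eta[:] = 0.0
            params.alpha_11_0[:] = 0.0
            params = gibbs_update_variances(ds, G, params, priors, rng)
            inv_draws.append(1.0 / params.sigma2)
        # 1/sigma2 ~ Gamma(1.01, rate 1.01): mean 1, sd 1/1.01/sqrt(1.01)
        assert np.mean(inv_draws) == pytest.approx(1.0, abs=0.06)
        assert np.all(np.array(inv_draws) > 0)

    def test_zero_cluster_effects_leave_prior_rate_for_tau2(self, rng):
        ds = make_dataset(n_clusters=4, size=2, treated=[0, 0, 1, 1])
        G = np.full(ds.n, G_NEVER)  # no observed-outcome rows used
        ds.S[:] = 0
        ds.Y[:] = np.nan
        priors = Priors(ig_shape=3.0, ig_rate=2.0)
        params = make_params(n_clusters=4)
        inv_draws = []
        for _ in range(6000):
            params.eta[:] = 0.0
            params = gibbs_update_variances(ds, G, params, priors, rng)
            inv_draws.append(1.0 / params.tau2)
        # tau2 ~ InvGamma(3 + 4/2, 2): E[1/tau2] = 5/2
        assert np.mean(inv_draws) == pytest.approx(2.5, rel=0.05)


def test_outcome_icc_values():
    assert outcome_icc(1.0, 5.0) == pytest.approx(1 / 6)
    assert round(outcome_icc(1.0, 5.0), 3) == 0.167
    assert outcome_icc(1e-12, 5.0) < 1e-9
    assert outcome_icc(5.0, 1e-12) > 1 - 1e-9
    with pytest.raises(ValueError):
        outcome_icc(0.0, 1.0)
    with pytest.raises(ValueError):
        outcome_icc(1.0, -1.0)
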
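"""Mixed-model likelihood, predictions and deviance partition."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import reefspawn as rs
from reefspawn.glmm import _GroupIndex, marginal_loglik


def _design(X, y, groups=None, columns=None):
    cols = columns or [f"x{i}" for i in range(X.shape[1])]
    return (pd.DataFrame(X, columns=cols), y, groups)


def _sim_mixed(n=20, n_groups=2, seed=0, beta=(0.3, 0.8), sigma=0.7):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    g = rng.integers(0, n_groups, n)
    u = rng.normal(0, sigma, n_groups)
    eta = X @ np.asarray(beta) + u[g]
    y = rng.binomial(1, expit(eta)).astype(float)
    return X, y, g


def trapezoid_marginal_loglik(X, y, groups, beta, sigma, nodes=10001, span=12.0):
    """Independent dense-integration oracle for the marginal likelihood."""
    eta0 = X @ beta
    total = 0.0
    u = np.linspace(-span * sigma, span * sigma, nodes)
    log_prior = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * (u / sigma) ** 2
    for gval in np.unique(groups):
        sel = groups == gval
        eta = eta0[sel][:, None] + u[None, :]
        s = np.sum(
            y[sel][:, None] * eta - np.log1p(np.exp(eta)), axis=0
        )
        integrand = np.exp(s + log_prior)
        total += np.log(np.trapezoid(integrand, u))
    return total


class TestLikelihood:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = rs.fit_glmm(_design(np.ones((100, 1)), y, columns=["Intercept"]))
        assert fit.params.iloc[0] == pytest.approx(np.log(3 / 7), abs=1e-9)
        assert fit.re_sd == 0.0
        assert fit.loglik == pytest.approx(
            30 * np.log(0.3) + 70 * np.log(0.7), abs=1e-8
        )

    @pytest.mark.parametrize("sigma", [0.3, 0.8, 1.5])
    def test_matches_dense_integration(self, sigma):
        X, y, g = _sim_mixed(n=20, n_groups=2, seed=3)
        gi = _GroupIndex(g)
        beta = np.array([0.2, 0.6])
        ll = marginal_loglik(X, y, gi, beta, sigma, n_quad=21)
        oracle = trapezoid_marginal_loglik(X, y, g, beta, sigma)
        assert ll == pytest.approx(oracle, abs=1e-4)

    def test_fitted_loglik_matches_oracle(self):
        X, y, g = _sim_mixed(n=20, n_groups=2, seed=5)
        fit = rs.fit_glmm(_design(X, y, g))
        if fit.re_sd > 1e-6:
            oracle = trapezoid_marginal_loglik(
                X, y, g, fit.params.to_numpy(), fit.re_sd
            )
            assert fit.loglik == pytest.approx(oracle, abs=1e-4)

    def test_laplace_is_one_node_agq(self):
        X, y, g = _sim_mixed(n=200, n_groups=8, seed=7)
        gi = _GroupIndex(g)
        beta = np.array([0.1, 0.5])
        ll1 = marginal_loglik(X, y, gi, beta, 0.6, n_quad=1)
        ll21 = marginal_loglik(X, y, gi, beta, 0.6, n_quad=21)
        # Laplace approximates well but not exactly
        assert ll1 == pytest.approx(ll21, abs=0.5)
        assert ll1 != ll21

    def test_single_group_collapses_to_plain_logistic(self):
        X, y, _ = _sim_mixed(n=300, n_groups=1, seed=9, sigma=0.0)
        g = np.zeros(300, dtype=int)
        fit_mixed = rs.fit_glmm(_design(X, y, g))
        fit_plain = rs.fit_glmm(_design(X, y, None))
        assert fit_mixed.re_sd == 0.0
        assert np.max(np.abs(fit_mixed.params - fit_plain.params)) < 1e-6

    def test_boundary_sd_matches_plain_logistic(self):
        # truly homogeneous groups: SD estimate collapses to the boundary
        rng = np.random.default_rng(11)
        n = 2000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        g = rng.integers(0, 4, n)
        y = rng.binomial(1, expit(X @ np.array([0.0, 1.0]))).astype(float)
        fit_mixed = rs.fit_glmm(_design(X, y, g))
        fit_plain = rs.fit_glmm(_design(X, y, None))
        if fit_mixed.re_sd < 1e-6:
            assert np.max(np.abs(fit_mixed.params - fit_plain.params)) < 1e-6
        else:  # tiny estimated SD still implies near-identical coefficients
            assert np.max(np.abs(fit_mixed.params - fit_plain.params)) < 1e-3

    def test_aic_identity(self):
        X, y, g = _sim_mixed(n=400, n_groups=5, seed=13)
        fit = rs.fit_glmm(_design(X, y, g))
        k = fit.n_fixed + (1 if fit.re_estimated else 0)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, abs=1e-9)
        assert fit.null_deviance >= fit.deviance - 1e-9

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            rs.fit_glmm(_design(np.ones((50, 1)), np.ones(50)))

    def test_separation_warns(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        X = np.column_stack([np.ones(40), x])
        with pytest.warns(UserWarning, match="separation"):
            fit = rs.fit_glmm(_design(X, y, None))
        assert fit.separation_flagged
        fitp = rs.fit_glmm(_design(X, y, None), penalty=True)
        assert np.max(np.abs(fitp.params)) < 15  # Firth keeps estimates finite


class TestPrediction:
    def test_inverse_link_at_zero_row(self):
        X, y, g = _sim_mixed(n=500, n_groups=4, seed=17)
        fit = rs.fit_glmm(_design(X, y, g))
        row = np.array([[1.0, 0.0]])
        p, _ = rs.predict_with_se(fit, row)
        b0 = fit.params.iloc[0]
        assert p[0] == pytest.approx(1 / (1 + np.exp(-b0)), abs=1e-12)

    def test_monotone_in_positive_coefficient(self):
        X, y, g = _sim_mixed(n=800, n_groups=4, seed=19, beta=(0.0, 1.2))
        fit = rs.fit_glmm(_design(X, y, g))
        xs = np.linspace(-2, 2, 20)
        rows = np.column_stack([np.ones(20), xs])
        p = rs.predict_proba(fit, rows)
        assert (np.diff(p) > 0).all()

    def test_se_matches_parametric_bootstrap(self):
        """Delta-method SE of the predicted probability agrees with the SD of
        10,000 coefficient draws from the fitted covariance."""
        X, y, _ = _sim_mixed(n=600, n_groups=1, seed=23, beta=(0.2, 0.7))
        fit = rs.fit_glmm(_design(X, y, None))
        rows = np.array([[1.0, 0.5], [1.0, -1.0], [1.0, 1.5]])
        p, se = rs.predict_with_se(fit, rows)
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(
            fit.params.to_numpy(), fit.cov_fixed, size=10000
        )
        boot = expit(rows @ draws.T)
        boot_sd = boot.std(axis=1)
        assert np.allclose(se, boot_sd, rtol=0.10)


class TestDevianceExplained:
    def _nested_fits(self, seed=29, n=600):
        rng = np.random.default_rng(seed)
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = rng.binomial(1, expit(-0.3 + 0.9 * x1)).astype(float)
        X0 = np.ones((n, 1))
        X1 = np.column_stack([X0, x1])
        X2 = np.column_stack([X1, x2])
        f0 = rs.fit_glmm(_design(X0, y, columns=["Intercept"]))
        f1 = rs.fit_glmm(_design(X1, y, columns=["Intercept", "x1"]))
        f2 = rs.fit_glmm(_design(X2, y, columns=["Intercept", "x1", "x2"]))
        return f0, f1, f2

    def test_telescoping_sum(self):
        f0, f1, f2 = self._nested_fits()
        tab = rs.deviance_explained([f0, f1, f2])
        assert tab["percent"].sum() == pytest.approx(tab.attrs["total_percent"], abs=1e-9)

    def test_null_model_total_zero(self):
        f0, _, _ = self._nested_fits()
        tab = rs.deviance_explained([f0])
        assert tab.attrs["total_percent"] == pytest.approx(0.0, abs=1e-9)

    def test_noise_term_contributes_little(self):
        """A pure-noise column adds < 0.1 median percent deviance at n=2000."""
        pcts = []
        for s in range(100):
            rng = np.random.default_rng(500 + s)
            n = 2000
            x1 = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            y = rng.binomial(1, expit(0.5 * x1)).astype(float)
            X1 = np.column_stack([np.ones(n), x1])
            X2 = np.column_stack([X1, noise])
            f1 = rs.fit_glmm(_design(X1, y, columns=["Intercept", "x1"]))
            f2 = rs.fit_glmm(
                _design(X2, y, columns=["Intercept", "x1", "noise"]), fit_null=False
            )
            pcts.append(100 * (f1.deviance - f2.deviance) / f1.null_deviance)
        assert np.median(pcts) < 0.1

    def test_non_nested_rejected(self):
        f0, f1, _ = self._nested_fits()
        with pytest.raises(ValueError):
            rs.deviance_explained([f1, f0])


class TestWaldIntervals:
    def test_interval_brackets_estimate(self):
        X, y, g = _sim_mixed(n=1000, n_groups=8, seed=31, sigma=0.6)
        fit = rs.fit_glmm(_design(X, y, g))
        lo, hi = fit.wald_interval("x1")
        assert lo < fit.params["x1"] < hi
        if fit.re_sd > 1e-6:
            lo_s, hi_s = fit.wald_interval("re_sd")
            assert lo_s < fit.re_sd < hi_s
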
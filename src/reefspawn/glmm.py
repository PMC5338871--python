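"""Logit-linked binomial mixed model with a single random intercept.

The response is the per-fish spawning flag; fixed effects are the dummy-coded
design columns and the grouping factor (sampling year) carries a Gaussian
random intercept u_j ~ N(0, sigma^2). The marginal likelihood

    L(beta, sigma) = prod_j  integral  prod_{i in j} Bernoulli(y_ij | logit^-1(x_ij beta + u))  phi(u; 0, sigma) du

is maximised directly, integrating each group's intercept by adaptive
Gauss-Hermite quadrature (nodes recentred/rescaled at the conditional mode,
as in lme4's nAGQ): with one node this reduces exactly to the Laplace
approximation, which is used automatically for many-group fits. When the
grouping has a single level, or the SD estimate hits zero, the fit coincides
with ordinary logistic regression (plain IRLS path).

AIC counts the fixed coefficients plus one variance parameter whenever the
random intercept was estimated. Deviance is -2 log L (the Bernoulli
saturated log-likelihood is zero), on the marginal scale throughout; the
null deviance comes from an intercept-only refit with the same random
structure, so per-term "percent deviance explained" partitions match how
nested model sequences are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .covariates import DesignMatrix

_DEFAULT_QUAD = 21
_LAPLACE_ABOVE = 40  # group count beyond which Laplace (1 node) is used


# ---------------------------------------------------------------------------
# Plain logistic path (IRLS), with optional Firth adjusted-score correction
# ---------------------------------------------------------------------------

def _irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    firth: bool = False,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
    beta0: np.ndarray | None = None,
):
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        XtW = X.T * w
        H = XtW @ X + ridge * np.eye(p)
        z = y - mu
        if firth:
            # hat diagonal h_i of W^1/2 X (X'WX)^-1 X' W^1/2
            Hinv = np.linalg.inv(H)
            h = np.einsum("ij,jk,ik->i", X, Hinv, XtW.T)
            z = z + h * (0.5 - mu)
        score = X.T @ z - ridge * beta
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        beta_new = beta + step
        if np.max(np.abs(step)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = X @ beta
    ll = float(np.sum(y * eta + log_expit(-eta)))
    return beta, ll, converged


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1+exp(eta)), numerically safe
    return y * eta + log_expit(-eta)


# ---------------------------------------------------------------------------
# Marginal likelihood via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

class _GroupIndex:
    """Row ordering by group so per-group sums are reduceat calls."""

    def __init__(self, groups: np.ndarray):
        labels, codes = np.unique(groups, return_inverse=True)
        order = np.argsort(codes, kind="stable")
        self.labels = labels
        self.codes = codes
        self.order = order
        self.sorted_codes = codes[order]
        self.starts = np.searchsorted(self.sorted_codes, np.arange(len(labels)))
        self.n_groups = len(labels)

    def group_sum(self, vec: np.ndarray) -> np.ndarray:
        """Sum a length-n (or n x k) array within groups."""
        return np.add.reduceat(vec[self.order], self.starts, axis=0)


def _conditional_modes(
    eta0: np.ndarray, y: np.ndarray, gi: _GroupIndex, sigma: float,
    u0: np.ndarray | None = None, max_iter: int = 60, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve for each group's conditional posterior mode of u, plus
    the curvature there. The objective is concave, so undamped Newton is
    safe."""
    u = np.zeros(gi.n_groups) if u0 is None else u0.copy()
    inv_var = 1.0 / sigma**2
    for _ in range(max_iter):
        mu = expit(eta0 + u[gi.codes])
        score = gi.group_sum(y - mu) - u * inv_var
        hess = gi.group_sum(mu * (1 - mu)) + inv_var
        step = score / hess
        u += step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(eta0 + u[gi.codes])
    hess = gi.group_sum(mu * (1 - mu)) + inv_var
    return u, hess


def marginal_loglik(
    X: np.ndarray,
    y: np.ndarray,
    gi: _GroupIndex,
    beta: np.ndarray,
    sigma: float,
    n_quad: int = _DEFAULT_QUAD,
    u0: np.ndarray | None = None,
    return_modes: bool = False,
    return_grad: bool = False,
):
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    With ``return_grad`` also returns the gradient with respect to
    ``(beta, sigma)``. The adaptive recentring parameters are held fixed in
    the differentiation: the quadrature value is invariant to where the
    nodes are centred up to the quadrature error itself, so this gradient is
    exact to that (negligible) error.
    """
    eta0 = X @ beta
    if sigma < 1e-8:
        ll = float(np.sum(_bernoulli_loglik(eta0, y)))
        out = [ll]
        if return_modes:
            out.append(np.zeros(gi.n_groups))
        if return_grad:
            out.append(np.r_[X.T @ (y - expit(eta0)), 0.0])
        return out[0] if len(out) == 1 else tuple(out)
    u_hat, hess = _conditional_modes(eta0, y, gi, sigma, u0=u0)
    tau = 1.0 / np.sqrt(hess)                       # (J,)
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    # u_jk = u_hat_j + sqrt(2) tau_j x_k
    u_nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]  # (J,K)
    eta = eta0[:, None] + u_nodes[gi.codes, :]      # (n,K)
    per_group = gi.group_sum(_bernoulli_loglik(eta, y[:, None]))  # (J,K)
    log_prior = (
        -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * (u_nodes / sigma) ** 2
    )
    log_terms = (
        per_group
        + log_prior
        + np.log(wts)[None, :]
        + nodes[None, :] ** 2
        + 0.5 * np.log(2.0)
        + np.log(tau)[:, None]
    )
    m = log_terms.max(axis=1, keepdims=True)
    ll_j = m[:, 0] + np.log(np.exp(log_terms - m).sum(axis=1))
    ll = float(ll_j.sum())
    out = [ll]
    if return_modes:
        out.append(u_hat)
    if return_grad:
        omega = np.exp(log_terms - ll_j[:, None])   # posterior node weights (J,K)
        resid = omega[gi.codes, :] * (y[:, None] - expit(eta))  # (n,K)
        g_beta = X.T @ resid.sum(axis=1)
        g_sigma = float(
            np.sum(omega * (-1.0 / sigma + u_nodes**2 / sigma**3))
        )
        out.append(np.r_[g_beta, g_sigma])
    return out[0] if len(out) == 1 else tuple(out)


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    params: pd.Series
    re_sd: float
    loglik: float
    aic: float
    deviance: float
    null_deviance: float
    n: int
    n_groups: int
    converged: bool
    columns: tuple[str, ...]
    group_effects: pd.Series | None = None
    group_labels: tuple | None = None
    re_estimated: bool = False
    n_quad: int = _DEFAULT_QUAD
    penalized: bool = False
    separation_flagged: bool = False
    design: DesignMatrix | None = field(default=None, repr=False)
    _ctx: dict = field(default_factory=dict, repr=False)
    _cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_fixed(self) -> int:
        return len(self.params)

    @property
    def cov(self) -> np.ndarray:
        """Covariance of (beta[, sigma]) from the numeric Hessian of the
        negative marginal log-likelihood, computed lazily."""
        if self._cov is None:
            self._cov = _numeric_cov(self)
        return self._cov

    @property
    def cov_fixed(self) -> np.ndarray:
        return self.cov[: self.n_fixed, : self.n_fixed]

    @property
    def re_sd_se(self) -> float:
        if not self.re_estimated or self.re_sd < 1e-8:
            return np.nan
        return float(np.sqrt(self.cov[-1, -1]))

    def wald_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        zc = norm.ppf(0.5 + level / 2)
        if name == "re_sd":
            # Wald on the log-SD scale (keeps the interval positive and has
            # better coverage for small group counts), then back-transform
            se = self.re_sd_se
            if not np.isfinite(se) or self.re_sd <= 0:
                return np.nan, np.nan
            half = zc * se / self.re_sd
            return self.re_sd * np.exp(-half), self.re_sd * np.exp(half)
        i = list(self.params.index).index(name)
        se = float(np.sqrt(self.cov_fixed[i, i]))
        return self.params.iloc[i] - zc * se, self.params.iloc[i] + zc * se


def _theta_loglik(fit: ModelFit):
    X, y, gi = fit._ctx["X"], fit._ctx["y"], fit._ctx.get("gi")
    if fit.re_estimated and fit.re_sd >= 1e-8:
        def f(theta):
            return marginal_loglik(X, y, gi, theta[:-1], abs(theta[-1]), fit.n_quad)
        theta0 = np.r_[fit.params.to_numpy(), fit.re_sd]
    else:
        def f(theta):
            return float(np.sum(_bernoulli_loglik(X @ theta, y)))
        theta0 = fit.params.to_numpy()
    return f, theta0


def _numeric_cov(fit: ModelFit) -> np.ndarray:
    """Observed-information covariance via central-difference Hessian."""
    f, theta0 = _theta_loglik(fit)
    p = len(theta0)
    hstep = 1e-4 * (1.0 + np.abs(theta0))
    H = np.zeros((p, p))
    f0 = f(theta0)
    # diagonal
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        ei = np.zeros(p); ei[i] = hstep[i]
        fp[i] = f(theta0 + ei)
        fm[i] = f(theta0 - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / hstep[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = hstep[i]
            ej = np.zeros(p); ej[j] = hstep[j]
            fpp = f(theta0 + ei + ej)
            fmm = f(theta0 - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * hstep[i] * hstep[j])
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return cov


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_glmm(
    design: DesignMatrix | tuple,
    n_quad: int = _DEFAULT_QUAD,
    penalty: bool = False,
    fit_null: bool = True,
) -> ModelFit:
    """Maximum (marginal) likelihood fit of the random-intercept logistic
    model.

    ``design`` is a :class:`~reefspawn.covariates.DesignMatrix` (or an
    ``(X_dataframe, y, groups)`` tuple). ``penalty`` turns on the weak
    separation penalty: Firth's adjusted score in the plain path, a weak
    ridge in the mixed path; the fit records that it was penalised.
    """
    if isinstance(design, DesignMatrix):
        Xdf, y, groups = design.X, design.y, design.groups
        dm = design
    else:
        Xdf, y, groups = design
        dm = None
    X = np.asarray(Xdf, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not (0 < y.sum() < n):
        raise ValueError("response must contain both classes")
    if n < p + 5:
        raise ValueError("too few rows for the number of parameters")
    columns = tuple(Xdf.columns) if hasattr(Xdf, "columns") else tuple(
        f"x{i}" for i in range(p)
    )

    gi = _GroupIndex(np.asarray(groups)) if groups is not None else None
    single_group = gi is None or gi.n_groups < 2

    # start from the plain logistic solution
    beta0, ll_plain, conv_plain = _irls_logistic(X, y, firth=penalty and single_group)
    separation = bool(np.max(np.abs(beta0)) > 25) or not conv_plain
    if separation and not penalty:
        warnings.warn(
            "possible complete separation: coefficients at extreme values; "
            "consider penalty=True",
            stacklevel=2,
        )

    if single_group:
        fit = _finish_plain(
            X, y, beta0, ll_plain, conv_plain, columns, gi, penalty, separation, dm
        )
    else:
        if gi.n_groups > _LAPLACE_ABOVE:
            n_quad = 1
        ridge = 1e-3 if penalty else 0.0

        def negll(theta):
            beta, sigma = theta[:-1], max(theta[-1], 0.0)
            ll, grad = marginal_loglik(X, y, gi, beta, sigma, n_quad, return_grad=True)
            pen = 0.5 * ridge * float(beta @ beta)
            g = -grad
            g[:-1] += ridge * beta
            return -ll + pen, g

        theta0 = np.r_[beta0, 0.4]
        bounds = [(None, None)] * p + [(0.0, None)]
        res = minimize(
            negll, theta0, method="L-BFGS-B", jac=True, bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        beta_hat, sigma_hat = res.x[:-1], float(res.x[-1])
        if sigma_hat < 1e-6:
            # boundary: collapse to the ordinary logistic fit
            beta_hat, ll_hat, conv = _irls_logistic(
                X, y, firth=penalty, beta0=beta_hat
            )
            sigma_hat = 0.0
            u_hat = np.zeros(gi.n_groups)
        else:
            ll_hat, u_hat = marginal_loglik(
                X, y, gi, beta_hat, sigma_hat, n_quad, return_modes=True
            )
            conv = bool(res.success)
        fit = ModelFit(
            params=pd.Series(beta_hat, index=list(columns)),
            re_sd=sigma_hat,
            loglik=ll_hat,
            aic=-2 * ll_hat + 2 * (p + 1),
            deviance=-2 * ll_hat,
            null_deviance=np.nan,
            n=n,
            n_groups=gi.n_groups,
            converged=conv,
            columns=columns,
            group_effects=pd.Series(u_hat, index=list(gi.labels)),
            group_labels=tuple(gi.labels),
            re_estimated=True,
            n_quad=n_quad,
            penalized=penalty,
            separation_flagged=separation,
            design=dm,
            _ctx={"X": X, "y": y, "gi": gi},
        )

    if fit_null:
        if p == 1:
            fit.null_deviance = fit.deviance
        else:
            null_design = (pd.DataFrame({"Intercept": np.ones(n)}), y, groups)
            null_fit = fit_glmm(null_design, n_quad=n_quad, fit_null=False)
            fit.null_deviance = null_fit.deviance
    return fit


def _finish_plain(X, y, beta, ll, conv, columns, gi, penalty, separation, dm) -> ModelFit:
    n, p = X.shape
    n_groups = 1 if gi is None else gi.n_groups
    return ModelFit(
        params=pd.Series(beta, index=list(columns)),
        re_sd=0.0,
        loglik=ll,
        aic=-2 * ll + 2 * p,
        deviance=-2 * ll,
        null_deviance=np.nan,
        n=n,
        n_groups=n_groups,
        converged=conv,
        columns=columns,
        group_effects=None,
        re_estimated=False,
        penalized=penalty,
        separation_flagged=separation,
        design=dm,
        _ctx={"X": X, "y": y},
    )


# ---------------------------------------------------------------------------
# Prediction and deviance partition
# ---------------------------------------------------------------------------

def predict_with_se(fit: ModelFit, Xnew) -> tuple[np.ndarray, np.ndarray]:
    """Population-level predicted probability and delta-method standard
    error for each new design row (random intercept set to zero)."""
    if hasattr(Xnew, "columns"):
        Xnew = Xnew.reindex(columns=list(fit.columns), fill_value=0.0)
    Xm = np.asarray(Xnew, dtype=float)
    eta = Xm @ fit.params.to_numpy()
    var_eta = np.einsum("ij,jk,ik->i", Xm, fit.cov_fixed, Xm)
    var_eta = np.clip(var_eta, 0.0, None)
    p = expit(eta)
    se = p * (1 - p) * np.sqrt(var_eta)
    return p, se


def predict_proba(fit: ModelFit, Xnew) -> np.ndarray:
    """Probabilities only (no covariance computation)."""
    if hasattr(Xnew, "columns"):
        Xnew = Xnew.reindex(columns=list(fit.columns), fill_value=0.0)
    return expit(np.asarray(Xnew, dtype=float) @ fit.params.to_numpy())


def deviance_explained(fit_sequence: list[ModelFit]) -> pd.DataFrame:
    """Percent deviance explained by each added term in a nested fit
    sequence: term i contributes 100 * (D_{i-1} - D_i) / D_null; the
    contributions telescope to the total."""
    if len(fit_sequence) < 1:
        raise ValueError("need at least one fit")
    n0 = fit_sequence[0].n
    if any(f.n != n0 for f in fit_sequence):
        raise ValueError("fits must share identical rows")
    prev_cols = set(fit_sequence[0].columns)
    for f in fit_sequence[1:]:
        cols = set(f.columns)
        if not prev_cols <= cols:
            raise ValueError("fit sequence is not nested")
        prev_cols = cols
    d_null = fit_sequence[0].null_deviance
    rows = []
    prev = fit_sequence[0]
    rows.append(
        {
            "step": 0,
            "terms": getattr(prev.design, "terms", ()),
            "deviance": prev.deviance,
            "percent": 100.0 * (d_null - prev.deviance) / d_null
            if len(prev.columns) > 1
            else 0.0,
        }
    )
    for i, f in enumerate(fit_sequence[1:], start=1):
        rows.append(
            {
                "step": i,
                "terms": getattr(f.design, "terms", ()),
                "deviance": f.deviance,
                "percent": 100.0 * (prev.deviance - f.deviance) / d_null,
            }
        )
        prev = f
    out = pd.DataFrame(rows)
    out.attrs["total_percent"] = 100.0 * (d_null - prev.deviance) / d_null
    out.attrs["null_deviance"] = d_null
    return out
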
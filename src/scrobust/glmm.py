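"""Random-intercept regression fits used by the hurdle test and score tests.

Two working models, each with a per-group (per-sample) random intercept:

* Gaussian: y = X b + u_g + e, u_g ~ N(0, s_b^2), e ~ N(0, s^2).  Fitted by
  maximum likelihood with b and s^2 profiled out in closed form (GLS) and a
  one-dimensional search over the variance ratio psi = s_b^2 / s^2.
* Logistic: logit P(y=1) = X b + u_g.  Fitted by a Laplace approximation to
  the marginal likelihood: for candidate (b, log tau) the per-group modes
  u_g are found by independent 1-d Newton steps (groups are conditionally
  independent), and the Laplace correction uses the per-group curvature.

Both return genuine marginal log-likelihoods so nested models can be
compared by likelihood ratio.  ``mode="fixed"`` drops the random intercept
and reduces to OLS / plain logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit

_MAX_LOGPSI = 8.0
_MIN_LOGPSI = -12.0


@dataclass
class RegressionFit:
    """Coefficients and marginal log-likelihood of one fitted part."""

    params: np.ndarray
    names: list[str]
    loglik: float
    sigma2: float | None = None  # residual variance (Gaussian part)
    re_var: float | None = None  # random-intercept variance
    converged: bool = True

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])


def _group_codes(groups: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    return codes, codes.max() + 1


# ---------------------------------------------------------------------------
# Gaussian part
# ---------------------------------------------------------------------------

def _gauss_profile(psi: float, X, y, codes, n_groups):
    """Profiled (over beta, sigma2) -2-free log-likelihood pieces for psi."""
    n, p = X.shape
    # V_g^{-1} = I - (psi / (1 + psi*m_g)) J ; apply via group sums
    m = np.bincount(codes, minlength=n_groups).astype(float)
    shrink = psi / (1.0 + psi * m)
    sx = np.zeros((n_groups, p))
    for j in range(p):
        sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_groups)
    sy = np.bincount(codes, weights=y, minlength=n_groups)
    xtvx = X.T @ X - sx.T @ (sx * shrink[:, None])
    xtvy = X.T @ y - sx.T @ (sy * shrink)
    beta = np.linalg.solve(xtvx, xtvy)
    r = y - X @ beta
    sr = np.bincount(codes, weights=r, minlength=n_groups)
    rss = float(r @ r - sr @ (sr * shrink))
    sigma2 = rss / n
    logdet = float(np.sum(np.log1p(psi * m)))
    loglik = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    return loglik, beta, sigma2


def fit_gaussian(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    groups: np.ndarray | None = None,
    mode: str = "mixed",
) -> RegressionFit:
    """ML Gaussian regression, optionally with a per-group random intercept."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if mode == "fixed" or groups is None:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sigma2 = max(float(r @ r) / n, 1e-300)
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        return RegressionFit(beta, names, ll, sigma2=sigma2, re_var=None)

    codes, n_groups = _group_codes(groups)

    def neg(logpsi: float) -> float:
        return -_gauss_profile(np.exp(logpsi), X, y, codes, n_groups)[0]

    res = minimize_scalar(
        neg, bounds=(_MIN_LOGPSI, _MAX_LOGPSI), method="bounded",
        options={"xatol": 1e-6},
    )
    psi = float(np.exp(res.x))
    ll, beta, sigma2 = _gauss_profile(psi, X, y, codes, n_groups)
    # boundary check: psi -> 0 reduces to OLS
    ll0, beta0, sigma20 = _gauss_profile(0.0, X, y, codes, n_groups)
    if ll0 >= ll:
        ll, beta, sigma2, psi = ll0, beta0, sigma20, 0.0
    return RegressionFit(
        beta, names, float(ll), sigma2=sigma2, re_var=psi * sigma2
    )


# ---------------------------------------------------------------------------
# Logistic part
# ---------------------------------------------------------------------------

def _logit_fixed(X, y, max_iter=50, ridge=1e-9):
    """Plain logistic regression by IRLS with a tiny ridge for stability."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        g = X.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    beta = np.clip(beta, -30, 30)
    eta = np.clip(X @ beta, -30, 30)
    ll = float(y @ eta - np.sum(np.log1p(np.exp(eta))))
    return beta, ll, converged


def _laplace_loglik(beta, tau2, X, y, codes, n_groups, n_newton=30):
    """Laplace marginal log-likelihood for fixed coefficients and tau^2."""
    xb = X @ beta
    u = np.zeros(n_groups)
    for _ in range(n_newton):
        eta = xb + u[codes]
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = np.bincount(codes, weights=y - mu, minlength=n_groups) - u / tau2
        hess = np.bincount(codes, weights=w, minlength=n_groups) + 1.0 / tau2
        step = grad / hess
        u += step
        if np.max(np.abs(step)) < 1e-9:
            break
    eta = np.clip(xb + u[codes], -30, 30)
    ll_data = float(y @ eta - np.sum(np.log1p(np.exp(eta))))
    mu = expit(eta)
    h = np.bincount(codes, weights=mu * (1 - mu), minlength=n_groups)
    penalty = float(np.sum(u**2) / (2 * tau2))
    correction = 0.5 * float(np.sum(np.log1p(tau2 * h)))
    return ll_data - penalty - correction


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    groups: np.ndarray | None = None,
    mode: str = "mixed",
    start: np.ndarray | None = None,
) -> RegressionFit:
    """ML logistic regression, optionally with a Laplace random intercept."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    p = X.shape[1]
    beta0, ll_fixed, conv = _logit_fixed(X, y)
    if mode == "fixed" or groups is None:
        return RegressionFit(beta0, names, ll_fixed, converged=conv)

    codes, n_groups = _group_codes(groups)

    def neg(theta: np.ndarray) -> float:
        beta, logtau = theta[:p], theta[p]
        tau2 = float(np.exp(2.0 * np.clip(logtau, -8, 3)))
        return -_laplace_loglik(beta, tau2, X, y, codes, n_groups)

    x0 = np.concatenate([beta0 if start is None else start, [np.log(0.3)]])
    res = minimize(neg, x0, method="BFGS", options={"maxiter": 200, "gtol": 1e-5})
    ll = -float(res.fun)
    # the tau -> 0 limit is the fixed fit; keep whichever is better so the
    # marginal likelihood never falls below its own boundary case
    if not np.isfinite(ll) or ll_fixed >= ll:
        return RegressionFit(beta0, names, ll_fixed, re_var=0.0, converged=conv)
    beta = res.x[:p]
    tau = float(np.exp(np.clip(res.x[p], -8, 3)))
    # BFGS "precision loss" exits sit at the optimum for all practical
    # purposes; only a non-finite objective marks a real failure
    return RegressionFit(beta, names, ll, re_var=tau**2, converged=True)
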
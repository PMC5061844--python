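"""Random-intercept mixed models by maximum likelihood.

Two families, one surface:

* **binomial** — per-fix foraging indicator.  The marginal likelihood
  integrates the random intercept out of the Bernoulli likelihood with
  *adaptive* Gauss-Hermite quadrature: for each group the integrand is
  re-centered at the mode of the joint log-density and re-scaled by the
  curvature there, so few nodes (default 9) give near-exact integrals.
* **normal** — efficiency / quality responses.  The marginal likelihood is
  Gaussian with per-group compound-symmetric covariance; fixed effects are
  profiled out in closed form (GLS) and the two variance components are
  optimized numerically.

Degrees of freedom are counted as fixed coefficients + 1 (random-intercept
variance) + 1 more for the residual variance in the normal family — the
convention used everywhere AICc is computed in this package.

The random-intercept standard deviation is optimized on the log scale; a
fit drifting to the boundary (sd effectively 0) is reported as a boundary
fit, not an error, and can be requested exactly with ``re_sd=0`` (the
model then collapses to an ordinary GLM/OLS fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import roots_hermite

__all__ = ["MixedFit", "fit_mixed", "binomial_loglik", "normal_loglik"]

_SQRT2 = np.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixedFit:
    """A fitted random-intercept mixed model."""

    family: str
    coef: np.ndarray
    re_sd: float
    sigma: float | None  # residual sd (normal family only)
    loglik: float
    df: int
    n: int
    n_groups: int
    converged: bool
    boundary: bool  # random-intercept variance at zero


class _GroupData:
    """Response/design sorted by group, with reduceat boundaries."""

    def __init__(self, y, X, groups):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        g = groups[order]
        change = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
        self.starts = change
        self.sizes = np.diff(np.r_[change, len(g)])
        self.n_groups = len(change)
        self.group_of = np.repeat(np.arange(self.n_groups), self.sizes)
        self.n, self.p = self.X.shape

    def group_sum(self, values):
        return np.add.reduceat(values, self.starts)


def _bernoulli_ll_terms(eta, y):
    # y*eta - log(1 + exp(eta)), stable for large |eta|
    return y * eta - np.logaddexp(0.0, eta)


def _binomial_group_loglik(gd: _GroupData, beta, sigma, nodes, weights):
    """Per-group integrated log-likelihoods via adaptive Gauss-Hermite."""
    eta0 = gd.X @ beta
    if sigma <= 0.0:
        return gd.group_sum(_bernoulli_ll_terms(eta0, gd.y))
    inv_var = 1.0 / (sigma * sigma)
    # Newton for the per-group joint mode u*
    u = np.zeros(gd.n_groups)
    for _ in range(50):
        eta = eta0 + u[gd.group_of]
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = gd.group_sum(gd.y - p) - u * inv_var
        hess = -gd.group_sum(p * (1.0 - p)) - inv_var
        step = grad / hess
        u = u - step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta = eta0 + u[gd.group_of]
    p = 1.0 / (1.0 + np.exp(-eta))
    curv = gd.group_sum(p * (1.0 - p)) + inv_var  # -g''(u*)
    scale = 1.0 / np.sqrt(curv)
    # g(u) at shifted nodes, for each group x node
    ll = np.empty((gd.n_groups, len(nodes)))
    for k, z in enumerate(nodes):
        uk = u + _SQRT2 * scale * z
        etak = eta0 + uk[gd.group_of]
        g = gd.group_sum(_bernoulli_ll_terms(etak, gd.y)) - 0.5 * uk * uk * inv_var
        ll[:, k] = g + z * z + np.log(weights[k])
    m = ll.max(axis=1)
    integral = np.log(np.sum(np.exp(ll - m[:, None]), axis=1)) + m
    return integral + np.log(_SQRT2 * scale) - np.log(sigma) - _LOG_SQRT_2PI


def binomial_loglik(beta, sigma, y, X, groups, n_quad: int = 9) -> float:
    """Integrated binomial random-intercept log-likelihood (AGQ)."""
    gd = _GroupData(y, X, groups)
    nodes, weights = roots_hermite(n_quad)
    return float(np.sum(_binomial_group_loglik(gd, np.asarray(beta, float), float(sigma),
                                               nodes, weights)))


def normal_loglik(beta, re_sd, sigma, y, X, groups) -> float:
    """Marginal Gaussian log-likelihood at given parameters."""
    gd = _GroupData(y, X, groups)
    r = gd.y - gd.X @ np.asarray(beta, float)
    return _normal_ll_resid(gd, r, float(re_sd) ** 2, float(sigma) ** 2)


def _normal_ll_resid(gd: _GroupData, r, var_b, var_e):
    c = var_b / (var_e + gd.sizes * var_b)  # Woodbury factor per group
    rsum = gd.group_sum(r)
    quad = (r @ r - np.sum(c * rsum * rsum)) / var_e
    logdet = np.sum((gd.sizes - 1) * np.log(var_e) + np.log(var_e + gd.sizes * var_b))
    return -0.5 * (logdet + quad + gd.n * np.log(2.0 * np.pi))


def _normal_profile(gd: _GroupData, var_b, var_e):
    """Profile beta out by GLS; return (beta, loglik)."""
    c = var_b / (var_e + gd.sizes * var_b)
    Xsum = np.add.reduceat(gd.X, gd.starts, axis=0)
    ysum = gd.group_sum(gd.y)
    XtVX = (gd.X.T @ gd.X - (Xsum * c[:, None]).T @ Xsum) / var_e
    XtVy = (gd.X.T @ gd.y - (Xsum * c[:, None]).T @ ysum) / var_e
    beta = np.linalg.solve(XtVX, XtVy)
    r = gd.y - gd.X @ beta
    return beta, _normal_ll_resid(gd, r, var_b, var_e)


def _fit_normal(gd: _GroupData, re_sd_fixed):
    resid0 = gd.y - gd.X @ np.linalg.lstsq(gd.X, gd.y, rcond=None)[0]
    s2 = max(float(np.var(resid0)), 1e-8)
    if re_sd_fixed is not None:
        vb = float(re_sd_fixed) ** 2

        def nll(q):
            return -_normal_profile(gd, vb, np.exp(q[0]))[1]

        res = optimize.minimize_scalar(lambda q: nll([q]),
                                       bracket=(np.log(s2) - 2, np.log(s2) + 2))
        ve = float(np.exp(res.x))
        beta, ll = _normal_profile(gd, vb, ve)
        return beta, np.sqrt(vb), np.sqrt(ve), ll, True, vb == 0.0

    def nll(q):
        return -_normal_profile(gd, np.exp(q[0]), np.exp(q[1]))[1]

    best = None
    for f in (0.5, 0.05):
        start = np.log([max(s2 * f, 1e-8), s2 * (1 - f if f < 1 else 0.5)])
        res = optimize.minimize(nll, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    vb, ve = np.exp(best.x)
    boundary = vb < 1e-7 * ve
    if boundary:
        # compare against the exact boundary fit and keep the better one
        res2 = optimize.minimize_scalar(lambda q: -_normal_profile(gd, 0.0, np.exp(q))[1],
                                        bracket=(np.log(ve) - 1, np.log(ve) + 1))
        if -res2.fun >= -best.fun - 1e-9:
            ve = float(np.exp(res2.x))
            beta, ll = _normal_profile(gd, 0.0, ve)
            return beta, 0.0, np.sqrt(ve), ll, True, True
    beta, ll = _normal_profile(gd, vb, ve)
    return beta, float(np.sqrt(vb)), float(np.sqrt(ve)), ll, True, boundary


def _glm_start(gd: _GroupData):
    """Plain logistic-regression start via Newton iterations."""
    beta = np.zeros(gd.p)
    for _ in range(25):
        eta = gd.X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-10, None)
        grad = gd.X.T @ (gd.y - p)
        hess = (gd.X * w[:, None]).T @ gd.X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _fit_binomial(gd: _GroupData, n_quad, re_sd_fixed):
    nodes, weights = roots_hermite(n_quad)
    if re_sd_fixed is not None and re_sd_fixed == 0.0:
        beta = _glm_start(gd)
        ll = float(np.sum(_bernoulli_ll_terms(gd.X @ beta, gd.y)))
        return beta, 0.0, ll, True, True

    def nll(params):
        beta, ls = params[:-1], params[-1]
        if abs(ls) > 20:
            return 1e300
        val = np.sum(_binomial_group_loglik(gd, beta, np.exp(ls), nodes, weights))
        return -val if np.isfinite(val) else 1e300

    start = np.append(_glm_start(gd), np.log(0.5))
    if re_sd_fixed is not None:

        def nll_fixed(beta):
            val = np.sum(_binomial_group_loglik(gd, beta, re_sd_fixed, nodes, weights))
            return -val if np.isfinite(val) else 1e300

        res = optimize.minimize(nll_fixed, start[:-1], method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        return res.x, float(re_sd_fixed), -float(res.fun), bool(res.success), False

    res = optimize.minimize(nll, start, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 1000})
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
    beta, sigma = res.x[:-1], float(np.exp(res.x[-1]))
    ll = -float(res.fun)
    boundary = sigma < 1e-4
    if boundary:
        beta0 = _glm_start(gd)
        ll0 = float(np.sum(_bernoulli_ll_terms(gd.X @ beta0, gd.y)))
        if ll0 >= ll - 1e-9:
            return beta0, 0.0, ll0, True, True
    if not converged:
        raise RuntimeError(
            f"binomial mixed model did not converge: |grad| = {np.max(np.abs(res.jac)):.3g}"
        )
    return beta, sigma, ll, converged, boundary


def fit_mixed(
    y,
    X,
    groups,
    family: str = "binomial",
    n_quad: int = 9,
    re_sd: float | None = None,
) -> MixedFit:
    """Fit a random-intercept mixed model by maximum likelihood.

    Parameters
    ----------
    y, X, groups
        Response, full-rank design matrix (including intercept), and group
        (animal) identifiers, all of length n.
    family
        ``"binomial"`` (Bernoulli response, AGQ-integrated likelihood) or
        ``"normal"`` (Gaussian, profiled GLS).
    n_quad
        Number of adaptive Gauss-Hermite nodes (binomial family).
    re_sd
        If given, the random-intercept sd is held fixed at this value
        instead of estimated (``0`` collapses to an ordinary GLM/OLS fit);
        the fixed value still counts in the df bookkeeping.
    """
    gd = _GroupData(y, X, groups)
    if gd.n_groups < 2 and re_sd is None:
        raise ValueError("need at least 2 groups to estimate a random intercept")
    if np.linalg.matrix_rank(gd.X) < gd.p:
        raise ValueError("design matrix is rank deficient")
    if family == "binomial":
        if n_quad < 2:
            raise ValueError("n_quad must be >= 2")
        beta, sd, ll, conv, boundary = _fit_binomial(gd, n_quad, re_sd)
        df = gd.p + 1
        return MixedFit("binomial", np.asarray(beta), float(sd), None, float(ll),
                        df, gd.n, gd.n_groups, conv, boundary)
    if family == "normal":
        beta, sd, sigma, ll, conv, boundary = _fit_normal(gd, re_sd)
        df = gd.p + 2
        return MixedFit("normal", np.asarray(beta), float(sd), float(sigma), float(ll),
                        df, gd.n, gd.n_groups, conv, boundary)
    raise ValueError(f"unknown family {family!r}")
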
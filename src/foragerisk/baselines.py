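"""Forage-availability baselines fitted on random berry plots.

Ripe-berry counts on 1-m2 plots are modeled with a zero-truncated negative
binomial (ZTNB) regression — field plots enter the fit only when they hold
at least one berry — and berry sugar content (%Brix) with ordinary least
squares.  Both models use habitat (mature forest vs clearcut) and Julian
date as predictors and are used to predict the forage expected at any
(habitat, day) combination, the reference against which foraging
efficiency and forage quality are measured.

The negative binomial uses the NB2 mean-dispersion parameterization with a
log link: Var(Y) = mu + mu^2/theta.  The zero-truncated pmf is

    P(Y = y | Y >= 1) = NB(y; mu, theta) / (1 - P0),   P0 = (theta/(theta+mu))^theta

and the truncated mean is mu / (1 - P0).  Maximum likelihood is obtained by
numerical optimization in (coefficients, log theta) space from several
starting points (method-of-moments theta and fixed theta in {0.5, 2, 10}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools import numdiff

from .config import HABITATS

__all__ = [
    "BaselineFit",
    "nb_logpmf",
    "ztnb_logpmf",
    "ztnb_loglik",
    "truncated_mean",
    "fit_ztnb",
    "fit_sugar",
    "predict_expected",
    "prediction_table",
]

_NEG_INF = -1e300  # sentinel for inadmissible parameter points


@dataclass(frozen=True)
class BaselineFit:
    """A fitted availability baseline (ZTNB counts or linear sugar).

    ``coef`` holds ``intercept`` (mature-forest level at the centering
    date), ``clearcut`` (habitat contrast) and ``julian`` (per-day slope);
    ``julian_center`` is the date-centering constant used in the linear
    predictor.  ``scale`` is the NB dispersion theta for the count model and
    the residual standard deviation for the sugar model.  ``cov`` is the
    estimated covariance of the parameter vector (count model: coefficients
    plus log theta; sugar model: coefficients only), used to propagate
    prediction uncertainty.
    """

    family: str  # "ztnb" | "linear"
    coef: dict[str, float]
    scale: float
    loglik: float
    n: int
    julian_center: float
    converged: bool = True
    cov: np.ndarray | None = field(default=None, repr=False)

    def to_json(self) -> str:
        """Serialize the fit (without the covariance) for output files."""
        import json

        return json.dumps(
            {
                "family": self.family,
                "coefficients": {k: float(v) for k, v in self.coef.items()},
                ("theta" if self.family == "ztnb" else "residual_sd"): float(self.scale),
                "loglik": float(self.loglik),
                "n": int(self.n),
                "julian_center": float(self.julian_center),
                "converged": bool(self.converged),
            },
            indent=2,
        )


def nb_logpmf(y, mu, theta):
    """NB2 log pmf with mean ``mu`` and dispersion ``theta``."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def _log_p0(mu, theta):
    return theta * np.log(theta / (theta + np.asarray(mu, dtype=float)))


def ztnb_logpmf(y, mu, theta):
    """Zero-truncated NB2 log pmf, defined for y >= 1."""
    log_p0 = _log_p0(mu, theta)
    return nb_logpmf(y, mu, theta) - np.log1p(-np.exp(log_p0))


def truncated_mean(mu, theta):
    """Mean of the zero-truncated NB2: mu / (1 - P0)."""
    return np.asarray(mu, dtype=float) / (-np.expm1(_log_p0(mu, theta)))


def _design(plots: pd.DataFrame, julian_center: float) -> np.ndarray:
    hab = plots["habitat"].to_numpy()
    unknown = set(hab) - set(HABITATS)
    if unknown:
        raise ValueError(f"unknown habitat level(s): {sorted(unknown)}")
    jd = plots["julian_date"].to_numpy(dtype=float) - julian_center
    return np.column_stack([np.ones(len(plots)), (hab == "clearcut").astype(float), jd])


def ztnb_loglik(
    params,
    plots: pd.DataFrame,
    julian_center: float | None = None,
    intercept_only: bool = False,
) -> float:
    """Zero-truncated NB log-likelihood of a plot table.

    ``params`` is ``(intercept, clearcut, julian, log_theta)`` on the
    log-mean scale, or ``(intercept, log_theta)`` with ``intercept_only``.
    All counts must be >= 1; a zero count is a caller error (truncate
    upstream — the baseline conditions on berry presence).  Inadmissible
    parameter points return a large negative sentinel instead of NaN so
    optimizers can recover.
    """
    y = plots["count"].to_numpy(dtype=float)
    if np.any(y < 1):
        raise ValueError(
            "ztnb_loglik requires counts >= 1; drop zero-count plots before fitting"
        )
    if julian_center is None:
        julian_center = float(plots["julian_date"].mean())
    params = np.asarray(params, dtype=float)
    beta, log_theta = params[:-1], params[-1]
    if not np.all(np.isfinite(params)) or log_theta < -30:
        return _NEG_INF
    # saturate the dispersion at the effective Poisson limit so the surface
    # stays flat (not cliff-edged) for equidispersed data
    log_theta = min(log_theta, 14.0)
    if intercept_only:
        eta = np.full(len(y), beta[0])
    else:
        eta = _design(plots, julian_center) @ beta
    if np.any(eta > 30):
        return _NEG_INF
    mu = np.exp(eta)
    ll = float(np.sum(ztnb_logpmf(y, mu, np.exp(log_theta))))
    return ll if np.isfinite(ll) else _NEG_INF


def _moment_start(plots: pd.DataFrame, julian_center: float) -> np.ndarray:
    y = plots["count"].to_numpy(dtype=float)
    m, v = float(np.mean(y)), float(np.var(y))
    theta0 = m * m / max(v - m, 1e-3)
    theta0 = float(np.clip(theta0, 0.05, 50.0))
    # crude log-mean regression ignoring truncation for the slope start
    X = _design(plots, julian_center)
    beta0, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    return np.append(beta0, np.log(theta0))


def fit_ztnb(plots: pd.DataFrame, min_n: int = 20, intercept_only: bool = False) -> BaselineFit:
    """Maximum-likelihood ZTNB fit of counts on habitat + Julian date.

    Runs Nelder-Mead then BFGS polish from a method-of-moments start and
    from fixed dispersion starts theta in {0.5, 2, 10}; keeps the best
    converged optimum.  Raises if no start converges.  With
    ``intercept_only`` the mean is a single constant (habitat and date
    coefficients fixed at zero).
    """
    if len(plots) < min_n:
        raise ValueError(f"need at least {min_n} truncated-count plots, got {len(plots)}")
    if not intercept_only and plots["habitat"].nunique() < 2:
        raise ValueError("count plots must span both habitat classes")
    julian_center = float(plots["julian_date"].mean())

    def nll(p):
        return -ztnb_loglik(p, plots, julian_center, intercept_only=intercept_only)

    if intercept_only:
        y = plots["count"].to_numpy(dtype=float)
        m, v = float(np.mean(y)), float(np.var(y))
        theta0 = float(np.clip(m * m / max(v - m, 1e-3), 0.05, 50.0))
        starts = [np.array([np.log(m), np.log(theta0)])]
    else:
        starts = [_moment_start(plots, julian_center)]
    for theta0 in (0.5, 2.0, 10.0):
        s = starts[0].copy()
        s[-1] = np.log(theta0)
        starts.append(s)

    best = None
    diagnostics = []
    for s in starts:
        nm = optimize.minimize(nll, s, method="Nelder-Mead",
                               options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        res = optimize.minimize(nll, nm.x, method="BFGS",
                                options={"gtol": 1e-7, "maxiter": 500})
        if res.fun > nm.fun:  # polish made it worse (flat/noisy region)
            res = nm
        diagnostics.append((res.fun, nm.success, res.success))
        # BFGS gradient tolerance relative to the objective's magnitude;
        # a converged simplex counts as convergence on flat surfaces
        ok = (
            nm.success
            or res.success
            or ("jac" in res and np.linalg.norm(res.jac) < 1e-5 * max(1.0, abs(res.fun)))
        )
        if ok and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"ZTNB fit failed to converge from all starts: {diagnostics}")

    hess = numdiff.approx_hess1(best.x, nll)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = None
    beta = best.x
    if intercept_only:
        coef = {"intercept": beta[0], "clearcut": 0.0, "julian": 0.0}
    else:
        coef = {"intercept": beta[0], "clearcut": beta[1], "julian": beta[2]}
    return BaselineFit(
        family="ztnb",
        coef=coef,
        scale=float(np.exp(beta[-1])),
        loglik=-float(best.fun),
        n=len(plots),
        julian_center=julian_center,
        converged=True,
        cov=cov if not intercept_only else None,
    )


def fit_sugar(plots: pd.DataFrame, min_n: int = 10) -> BaselineFit:
    """OLS fit of sugar (%Brix) on habitat + Julian date."""
    import statsmodels.api as sm

    sub = plots.dropna(subset=["sugar"])
    if len(sub) < min_n:
        raise ValueError(f"need at least {min_n} sugar plots, got {len(sub)}")
    julian_center = float(sub["julian_date"].mean())
    X = _design(sub, julian_center)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "rank-deficient sugar design: habitat and julian_date are collinear "
            "(single habitat level or a single sampling date)"
        )
    res = sm.OLS(sub["sugar"].to_numpy(dtype=float), X).fit()
    with np.errstate(divide="ignore", invalid="ignore"):  # saturated fits
        sigma = float(np.sqrt(res.scale)) if res.df_resid > 0 else 0.0
        loglik = float(res.llf) if res.df_resid > 0 else float("inf")
        cov = np.asarray(res.cov_params()) if res.df_resid > 0 else None
    return BaselineFit(
        family="linear",
        coef={"intercept": res.params[0], "clearcut": res.params[1], "julian": res.params[2]},
        scale=sigma,
        loglik=loglik,
        n=len(sub),
        julian_center=julian_center,
        converged=True,
        cov=cov,
    )


def _linpred(fit: BaselineFit, habitat, julian_date):
    habitat = np.asarray(habitat)
    unknown = set(np.atleast_1d(habitat).tolist()) - set(HABITATS)
    if unknown:
        raise ValueError(f"unknown habitat level(s): {sorted(unknown)}")
    jd = np.asarray(julian_date, dtype=float) - fit.julian_center
    return (
        fit.coef["intercept"]
        + fit.coef["clearcut"] * (habitat == "clearcut").astype(float)
        + fit.coef["julian"] * jd
    )


def predict_expected(fit: BaselineFit, habitat, julian_date, scale: str = "truncated"):
    """Expected forage at (habitat, julian_date) under a fitted baseline.

    For the count model, ``scale="truncated"`` (default) returns the mean
    of the zero-truncated distribution — the expectation on the scale the
    field protocol observes, since only plots holding berries enter the
    baseline — while ``scale="mean"`` returns the untruncated NB mean mu.
    For the sugar model the linear predictor is returned.
    """
    eta = _linpred(fit, habitat, julian_date)
    if fit.family == "linear":
        return eta
    mu = np.exp(eta)
    if scale == "truncated":
        return truncated_mean(mu, fit.scale)
    if scale == "mean":
        return mu
    raise ValueError("scale must be 'truncated' or 'mean'")


def prediction_variance(fit: BaselineFit, habitat, julian_date, scale: str = "truncated"):
    """Delta-method variance of the predicted expectation.

    Propagates the parameter covariance of the fitted baseline to the
    prediction; used so that efficiency summaries account for the shared
    uncertainty of the availability curve.
    """
    if fit.cov is None:
        return np.zeros(np.broadcast(np.asarray(habitat), np.asarray(julian_date)).shape)

    def pred_at(params):
        if fit.family == "linear":
            f2 = BaselineFit(fit.family, dict(zip(("intercept", "clearcut", "julian"), params)),
                             fit.scale, fit.loglik, fit.n, fit.julian_center, cov=None)
        else:
            f2 = BaselineFit(fit.family, dict(zip(("intercept", "clearcut", "julian"), params[:3])),
                             float(np.exp(params[3])), fit.loglik, fit.n, fit.julian_center, cov=None)
        return np.atleast_1d(predict_expected(f2, habitat, julian_date, scale=scale))

    if fit.family == "linear":
        p0 = np.array([fit.coef["intercept"], fit.coef["clearcut"], fit.coef["julian"]])
    else:
        p0 = np.array([fit.coef["intercept"], fit.coef["clearcut"], fit.coef["julian"],
                       np.log(fit.scale)])
    grad = numdiff.approx_fprime(p0, pred_at)  # shape (n_pred, n_params)
    grad = np.atleast_2d(grad)
    var = np.einsum("ij,jk,ik->i", grad, fit.cov, grad)
    return np.clip(var, 0.0, None)


def prediction_table(count_fit: BaselineFit, sugar_fit: BaselineFit,
                     julian_dates, scale: str = "truncated") -> pd.DataFrame:
    """Per-day per-habitat expected berries and sugar over a date range."""
    rows = []
    for jd in julian_dates:
        for hab in HABITATS:
            rows.append(
                {
                    "julian_date": int(jd),
                    "habitat": hab,
                    "expected_count": float(predict_expected(count_fit, hab, jd, scale=scale)),
                    "expected_sugar": float(predict_expected(sugar_fit, hab, jd)),
                }
            )
    return pd.DataFrame(rows)
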
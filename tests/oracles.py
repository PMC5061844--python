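"""Independent oracle implementations used only by the test suite.

Each oracle recomputes a quantity by a different route than the package:
a Michalsky-style almanac solar position with numerical crossing search,
a de Boor B-spline recursion, brute-force pmf summation / numerical
integration, and plain normal-equation least squares.  They share no code
with the implementation they check.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm


# --- solar: Michalsky (1988) approximate almanac algorithm ----------------

def solar_elevation_almanac(lat: float, lon: float, dt_utc: datetime) -> float:
    """Solar elevation (degrees) from the approximate almanac formulas."""
    y, m, d = dt_utc.year, dt_utc.month, dt_utc.day
    hour = dt_utc.hour + dt_utc.minute / 60 + dt_utc.second / 3600 + dt_utc.microsecond / 3.6e9
    delta = y - 1949
    leap = int(delta / 4)
    jd = 2432916.5 + delta * 365 + leap + (datetime(y, m, d) - datetime(y, 1, 1)).days + 1 + hour / 24
    n = jd - 2451545.0
    L = (280.460 + 0.9856474 * n) % 360
    g = np.radians((357.528 + 0.9856003 * n) % 360)
    lam = np.radians((L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g)) % 360)
    eps = np.radians(23.439 - 0.0000004 * n)
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    gmst = (6.697375 + 0.0657098242 * n + hour) % 24
    lmst = (gmst + lon / 15) % 24
    ha = np.radians(lmst * 15) - ra
    latr = np.radians(lat)
    el = np.arcsin(np.sin(dec) * np.sin(latr) + np.cos(dec) * np.cos(latr) * np.cos(ha))
    return float(np.degrees(el))


def solar_crossing_almanac(lat, lon, d, target_el, rising, utc_offset):
    """Local-clock time the sun crosses an elevation, by root finding.

    Returns None when no crossing exists in the searched half-day (polar
    or grazing conditions).
    """
    base = datetime(d.year, d.month, d.day) - timedelta(hours=utc_offset)
    lo, hi = (-2.0, 14.0) if rising else (10.0, 26.0)

    def f(h):
        return solar_elevation_almanac(lat, lon, base + timedelta(hours=h)) - target_el

    hs = np.linspace(lo, hi, 193)
    vals = [f(h) for h in hs]
    for i in range(len(hs) - 1):
        crosses = vals[i] < 0 <= vals[i + 1] if rising else vals[i] >= 0 > vals[i + 1]
        if crosses:
            r = brentq(f, hs[i], hs[i + 1], xtol=1e-7)
            return base + timedelta(hours=r) + timedelta(hours=utc_offset)
    return None


# --- B-splines: de Boor recursion -----------------------------------------

def bspline_basis_recursive(x: float, knots: np.ndarray, degree: int) -> np.ndarray:
    """All basis function values at x via the Cox-de Boor recursion."""
    t = np.asarray(knots, dtype=float)
    nb = len(t) - degree - 1
    # degree-0 indicator functions (right-closed at the final interval)
    b = np.zeros((len(t) - 1,))
    for i in range(len(t) - 1):
        if t[i] <= x < t[i + 1]:
            b[i] = 1.0
        elif x == t[-1] and t[i] < t[i + 1] and t[i + 1] == t[-1]:
            b[i] = 1.0
    for k in range(1, degree + 1):
        nb_k = len(t) - k - 1
        new = np.zeros(nb_k)
        for i in range(nb_k):
            left = 0.0
            if t[i + k] > t[i]:
                left = (x - t[i]) / (t[i + k] - t[i]) * b[i]
            right = 0.0
            if t[i + k + 1] > t[i + 1]:
                right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * b[i + 1]
            new[i] = left + right
        b = new
    return b[:nb]


# --- zero-truncated NB: brute-force pmf -----------------------------------

def ztnb_pmf_bruteforce(y: np.ndarray, mu, theta) -> np.ndarray:
    """Zero-truncated NB2 pmf from scipy.stats.nbinom, renormalized."""
    from scipy.stats import nbinom

    p = theta / (theta + mu)
    p0 = nbinom.pmf(0, theta, p)
    return nbinom.pmf(y, theta, p) / (1.0 - p0)


def ztnb_truncated_mean_bruteforce(mu, theta, ymax: int = 10**6) -> float:
    """Truncated mean by direct pmf summation."""
    y = np.arange(1, ymax + 1)
    pm = ztnb_pmf_bruteforce(y, mu, theta)
    return float(np.sum(y * pm))


# --- binomial GLMM: fine-grid marginal likelihood -------------------------

def binomial_glmm_loglik_grid(beta, sigma, y, X, groups, half_width=8.0, n_grid=40001):
    """Integrated Bernoulli random-intercept log-likelihood by trapezoid rule."""
    beta = np.asarray(beta, float)
    total = 0.0
    grid = np.linspace(-half_width * sigma, half_width * sigma, n_grid)
    w = norm.pdf(grid, 0.0, sigma)
    for j in np.unique(groups):
        m = np.asarray(groups) == j
        eta = X[m] @ beta
        f = np.array(
            [np.sum(y[m] * (eta + u) - np.logaddexp(0.0, eta + u)) for u in grid]
        )
        total += np.log(np.trapezoid(np.exp(f) * w, grid))
    return float(total)


# --- least squares: normal equations --------------------------------------

def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)
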
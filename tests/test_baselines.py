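"""ZTNB and linear availability baselines: likelihood, fits, predictions."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from foragerisk import baselines
from foragerisk.baselines import (
    fit_sugar,
    fit_ztnb,
    predict_expected,
    truncated_mean,
    ztnb_loglik,
    ztnb_logpmf,
)
from foragerisk.config import SimConfig
from foragerisk.synthetic import generate_berry_field
from oracles import ols_normal_equations, ztnb_pmf_bruteforce


def test_ztp_limit_probability_of_one():
    """mu=1, theta -> infinity: P(Y=1) approaches e^-1/(1 - e^-1)."""
    p1 = np.exp(ztnb_logpmf(1, 1.0, 1e8))
    assert p1 == pytest.approx(np.exp(-1) / (1 - np.exp(-1)), abs=1e-6)


@pytest.mark.parametrize("mu,theta", [(0.7, 0.4), (5.0, 2.5), (40.0, 12.0)])
def test_truncated_pmf_normalizes(mu, theta):
    y = np.arange(1, 10**6)
    assert np.exp(ztnb_logpmf(y, mu, theta)).sum() == pytest.approx(1.0, abs=1e-6)


def test_loglik_equals_per_observation_pmf_summation_oracle():
    cfg = replace(SimConfig(), seed=2)
    plots = generate_berry_field(cfg, 120)
    params = np.array([2.3, 0.8, 0.01, np.log(1.9)])
    center = float(plots["julian_date"].mean())
    ll = ztnb_loglik(params, plots, center)
    mu = np.exp(
        params[0]
        + params[1] * (plots["habitat"] == "clearcut").to_numpy(float)
        + params[2] * (plots["julian_date"].to_numpy(float) - center)
    )
    oracle = float(
        np.sum(np.log(ztnb_pmf_bruteforce(plots["count"].to_numpy(), mu, np.exp(params[-1]))))
    )
    assert ll == pytest.approx(oracle, abs=1e-10)


def test_loglik_rejects_zero_counts():
    plots = pd.DataFrame(
        {"habitat": ["clearcut"], "julian_date": [230], "count": [0]}
    )
    with pytest.raises(ValueError, match="zero"):
        ztnb_loglik(np.array([1.0, 0.0, 0.0, 0.0]), plots)


def test_ztnb_parameter_recovery_within_three_se():
    cfg = replace(SimConfig(), seed=0)
    plots = generate_berry_field(cfg, 2000)
    fit = fit_ztnb(plots)
    bp = cfg.berry_params
    true = np.array(
        [
            bp.count_log_intercepts["mature_forest"]
            + bp.count_date_slope * (fit.julian_center - bp.ref_julian),
            bp.count_log_intercepts["clearcut"] - bp.count_log_intercepts["mature_forest"],
            bp.count_date_slope,
            np.log(bp.count_theta),
        ]
    )
    est = np.array(
        [fit.coef["intercept"], fit.coef["clearcut"], fit.coef["julian"], np.log(fit.scale)]
    )
    se = np.sqrt(np.diag(fit.cov))
    assert np.all(np.abs(est - true) < 3 * se)


def test_mle_loglik_beats_generating_parameters():
    cfg = replace(SimConfig(), seed=4)
    plots = generate_berry_field(cfg, 400)
    fit = fit_ztnb(plots)
    bp = cfg.berry_params
    truth_params = np.array(
        [
            bp.count_log_intercepts["mature_forest"]
            + bp.count_date_slope * (fit.julian_center - bp.ref_julian),
            bp.count_log_intercepts["clearcut"] - bp.count_log_intercepts["mature_forest"],
            bp.count_date_slope,
            np.log(bp.count_theta),
        ]
    )
    assert fit.loglik >= ztnb_loglik(truth_params, plots, fit.julian_center) - 1e-6


def test_intercept_only_mle_matches_dense_grid_oracle():
    rng = np.random.default_rng(3)
    mu0, th0 = 9.0, 1.8
    counts = []
    while len(counts) < 400:
        c = int(rng.negative_binomial(th0, th0 / (th0 + mu0)))
        if c >= 1:
            counts.append(c)
    toy = pd.DataFrame({"habitat": "mature_forest", "julian_date": 230, "count": counts})
    fit = fit_ztnb(toy, intercept_only=True)
    # independent dense grid around the method-of-moments point
    y = np.asarray(counts, float)
    m, v = y.mean(), y.var()
    c0 = np.log(m)
    t0 = np.log(np.clip(m * m / max(v - m, 1e-3), 0.05, 50.0))
    g1 = np.arange(c0 - 0.5, c0 + 0.5, 5e-4)
    g2 = np.arange(t0 - 1.0, t0 + 1.0, 5e-4)
    lls = np.array(
        [
            [np.sum(ztnb_logpmf(y, np.exp(a), np.exp(b))) for b in g2[::20]]
            for a in g1[::20]
        ]
    )
    ia, ib = np.unravel_index(np.argmax(lls), lls.shape)
    # refine on the fine grid around the coarse optimum
    fa = g1[np.abs(g1 - g1[::20][ia]) < 0.02]
    fb = g2[np.abs(g2 - g2[::20][ib]) < 0.02]
    fine = np.array([[np.sum(ztnb_logpmf(y, np.exp(a), np.exp(b))) for b in fb] for a in fa])
    ja, jb = np.unravel_index(np.argmax(fine), fine.shape)
    assert abs(fa[ja] - fit.coef["intercept"]) < 1e-3
    assert abs(fb[jb] - np.log(fit.scale)) < 1e-3


def test_sugar_fit_matches_normal_equations_oracle():
    cfg = replace(SimConfig(), seed=6)
    plots = generate_berry_field(cfg, 300, sugar_fraction=1.0)
    fit = fit_sugar(plots)
    X = np.column_stack(
        [
            np.ones(len(plots)),
            (plots["habitat"] == "clearcut").to_numpy(float),
            plots["julian_date"].to_numpy(float) - fit.julian_center,
        ]
    )
    beta = ols_normal_equations(X, plots["sugar"].to_numpy(float))
    assert fit.coef["intercept"] == pytest.approx(beta[0], abs=1e-10)
    assert fit.coef["clearcut"] == pytest.approx(beta[1], abs=1e-10)
    assert fit.coef["julian"] == pytest.approx(beta[2], abs=1e-10)


def test_three_points_three_coefficients_interpolate_exactly():
    plots = pd.DataFrame(
        {
            "habitat": ["mature_forest", "clearcut", "mature_forest"],
            "julian_date": [220, 230, 240],
            "count": [5, 5, 5],
            "sugar": [7.0, 9.5, 8.0],
        }
    )
    fit = fit_sugar(plots, min_n=3)
    pred = predict_expected(fit, plots["habitat"].to_numpy(), plots["julian_date"].to_numpy())
    np.testing.assert_allclose(pred, plots["sugar"], atol=1e-9)


def test_rank_deficient_sugar_design_raises():
    plots = pd.DataFrame(
        {
            "habitat": ["mature_forest"] * 12,
            "julian_date": [230] * 12,
            "count": [3] * 12,
            "sugar": np.linspace(6, 9, 12),
        }
    )
    with pytest.raises(ValueError, match="collinear"):
        fit_sugar(plots)


def test_truncated_mean_exceeds_mu_and_matches_summation():
    for mu, theta in [(0.5, 0.7), (4.0, 2.0), (25.0, 3.0)]:
        tm = truncated_mean(mu, theta)
        assert tm > mu
        y = np.arange(1, 500_000)
        oracle = float(np.sum(y * np.exp(ztnb_logpmf(y, mu, theta))))
        assert tm == pytest.approx(oracle, abs=1e-6)


def test_prediction_monotone_in_date_for_fixed_habitat():
    cfg = replace(SimConfig(), seed=8)
    plots = generate_berry_field(cfg, 600)
    fit = fit_ztnb(plots)
    days = np.arange(219, 247)
    preds = predict_expected(fit, np.repeat("clearcut", len(days)), days)
    diffs = np.diff(preds)
    assert np.all(diffs > 0) if fit.coef["julian"] > 0 else np.all(diffs < 0)


def test_unknown_habitat_rejected():
    cfg = replace(SimConfig(), seed=8)
    plots = generate_berry_field(cfg, 100)
    fit = fit_ztnb(plots)
    with pytest.raises(ValueError, match="habitat"):
        predict_expected(fit, "bog", 230)


def test_ztnb_cross_check_against_statsmodels_truncated_model():
    """Independent route: statsmodels' zero-truncated NB MLE on one sample."""
    from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

    cfg = replace(SimConfig(), seed=12)
    plots = generate_berry_field(cfg, 800)
    fit = fit_ztnb(plots)
    X = np.column_stack(
        [
            np.ones(len(plots)),
            (plots["habitat"] == "clearcut").to_numpy(float),
            plots["julian_date"].to_numpy(float) - fit.julian_center,
        ]
    )
    sm_fit = TruncatedLFNegativeBinomialP(
        plots["count"].to_numpy(float), X, truncation=0, p=2
    ).fit(disp=0, maxiter=500)
    assert fit.coef["intercept"] == pytest.approx(sm_fit.params[0], abs=5e-3)
    assert fit.coef["clearcut"] == pytest.approx(sm_fit.params[1], abs=5e-3)
    # statsmodels parameterizes dispersion as alpha = 1/theta
    assert fit.scale == pytest.approx(1.0 / sm_fit.params[-1], rel=2e-2)


def test_large_theta_ztnb_agrees_with_truncated_poisson_mu():
    """Poisson-like data: fitted ZTNB mean matches a ZT-Poisson fit's mu."""
    from scipy import optimize, special

    rng = np.random.default_rng(5)
    lam = 6.0
    counts = rng.poisson(lam, 3000)
    counts = counts[counts >= 1][:1500]
    toy = pd.DataFrame({"habitat": "mature_forest", "julian_date": 230, "count": counts})
    fit = fit_ztnb(toy, intercept_only=True)

    def ztp_nll(log_mu):
        mu = np.exp(log_mu)
        ll = counts * np.log(mu) - mu - special.gammaln(counts + 1) - np.log1p(-np.exp(-mu))
        return -np.sum(ll)

    res = optimize.minimize_scalar(ztp_nll, bracket=(1.0, 2.5))
    mu_ztp = float(np.exp(res.x))
    se = mu_ztp / np.sqrt(len(counts))
    assert abs(np.exp(fit.coef["intercept"]) - mu_ztp) < 2 * se
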
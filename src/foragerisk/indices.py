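"""Foraging efficiency and forage quality indices.

*Efficiency* is the observed ripe-berry count at a used foraging location
minus the count expected from the availability baseline for that habitat
and day (berries per m2; positive means the bear used a better-than-
available patch).  *Quality* is the analogous difference on the sugar
scale (%Brix).

For modeling, efficiencies may be square-root transformed; negative values
are handled by adding a constant c = ceil(|min|) + 1 before the root and
subtracting it again after back-transformation, with c recorded so the
transform is exactly invertible.

``lag_check`` validates the field protocol: plots were visited 1-9 days
(median 3) after the bear, and efficiency must not drift with that delay —
the per-period least-squares slope of efficiency on lag should have a 95%
confidence interval covering zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import BaselineFit, predict_expected, prediction_variance

__all__ = [
    "efficiency",
    "quality",
    "sqrt_transform",
    "back_transform",
    "build_efficiency_table",
    "cell_summary",
    "LagCheck",
    "lag_check",
]


def efficiency(observed, expected):
    """Observed minus expected berry count (berries per m2); may be < 0."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(observed < 0):
        raise ValueError("observed berry counts cannot be negative")
    return observed - expected


def quality(observed_sugar, expected_sugar):
    """Observed minus expected sugar content (%Brix difference)."""
    observed_sugar = np.asarray(observed_sugar, dtype=float)
    if np.any(observed_sugar < 0):
        raise ValueError("observed sugar content cannot be negative")
    return observed_sugar - np.asarray(expected_sugar, dtype=float)


def sqrt_transform(values) -> tuple[np.ndarray, float]:
    """Square-root transform with an additive constant for negatives.

    Returns ``(sqrt(values + c), c)`` with c = ceil(|min|) + 1 when the
    minimum is negative and c = 1 otherwise, so the argument of the root
    is always >= 1 ... strictly positive.  Invert with
    :func:`back_transform`.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("sqrt_transform requires finite values")
    vmin = float(values.min()) if values.size else 0.0
    c = float(math.ceil(abs(vmin)) + 1) if vmin < 0 else 1.0
    shifted = values + c
    if np.any(shifted < 0):  # guarded: impossible by construction of c
        raise AssertionError("internal error: negative value after adding constant")
    return np.sqrt(shifted), c


def back_transform(transformed, c: float) -> np.ndarray:
    """Invert :func:`sqrt_transform`: t**2 - c."""
    t = np.asarray(transformed, dtype=float)
    return t * t - c


def build_efficiency_table(
    observations: pd.DataFrame,
    count_fit: BaselineFit,
    sugar_fit: BaselineFit | None = None,
    scale: str = "truncated",
) -> pd.DataFrame:
    """Join observations with baseline predictions and compute the indices.

    ``observations`` needs ``habitat``, ``julian_date``, ``count`` and
    optionally ``sugar`` columns (plus any id/period/bout columns, which
    pass through).  Adds ``expected_count``, ``efficiency``, and — when a
    sugar baseline is given — ``expected_sugar`` and ``quality``, plus the
    sqrt-transformed efficiency with its constant in ``constant_c``.
    """
    out = observations.copy()
    out["expected_count"] = predict_expected(
        count_fit, out["habitat"].to_numpy(), out["julian_date"].to_numpy(), scale=scale
    )
    out["efficiency"] = efficiency(out["count"].to_numpy(), out["expected_count"].to_numpy())
    if sugar_fit is not None and "sugar" in out.columns:
        out["expected_sugar"] = predict_expected(
            sugar_fit, out["habitat"].to_numpy(), out["julian_date"].to_numpy()
        )
        measured = out["sugar"].notna()
        q = np.full(len(out), np.nan)
        q[measured.to_numpy()] = quality(
            out.loc[measured, "sugar"].to_numpy(),
            out.loc[measured, "expected_sugar"].to_numpy(),
        )
        out["quality"] = q
    transformed, c = sqrt_transform(out["efficiency"].to_numpy())
    out["transformed_efficiency"] = transformed
    out["constant_c"] = c
    return out


def cell_summary(
    table: pd.DataFrame,
    count_fit: BaselineFit | None = None,
    value: str = "efficiency",
    scale: str = "truncated",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-(period, bout) mean of an index with a confidence interval.

    The interval combines the within-cell sampling variance of the mean
    with the (shared) delta-method variance of the baseline prediction
    averaged over the cell, when ``count_fit`` with a parameter covariance
    is supplied.  Without it the interval is the ordinary normal interval
    on the cell mean.
    """
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    for (period, bout), grp in table.groupby(["period", "bout"], sort=True):
        vals = grp[value].dropna().to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals)) if n else np.nan
        var_mean = float(np.var(vals, ddof=1) / n) if n > 1 else np.nan
        var_pred = 0.0
        if count_fit is not None and count_fit.cov is not None and n:
            pv = prediction_variance(
                count_fit,
                grp.loc[grp[value].notna(), "habitat"].to_numpy(),
                grp.loc[grp[value].notna(), "julian_date"].to_numpy(),
                scale=scale,
            )
            # the baseline error is shared across the cell: average its
            # variance contribution rather than dividing by n
            var_pred = float(np.mean(pv))
        se = float(np.sqrt(var_mean + var_pred)) if n > 1 else np.nan
        rows.append(
            {
                "period": period,
                "bout": bout,
                "n": n,
                "mean": mean,
                "se": se,
                "ci_low": mean - z * se if n > 1 else np.nan,
                "ci_high": mean + z * se if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LagCheck:
    """Slope of efficiency on sampling lag for one period, with 95% CI."""

    period: str
    slope: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def contains_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


def lag_check(table: pd.DataFrame, value: str = "efficiency", min_n: int = 10) -> list[LagCheck]:
    """Sampling-lag validation: regress the index on lag days, per period.

    Fits ``value ~ lag_days`` by OLS separately for the prehunting and
    hunting periods and reports the slope with its 95% confidence
    interval; a CI covering zero means the sampling delay did not bias the
    index.
    """
    import statsmodels.api as sm

    out = []
    for period, grp in table.groupby("period", sort=True):
        sub = grp.dropna(subset=[value, "lag_days"])
        if len(sub) < min_n:
            raise ValueError(f"period {period!r} has only {len(sub)} records (< {min_n})")
        lag = sub["lag_days"].to_numpy(dtype=float)
        if np.ptp(lag) == 0:
            raise ValueError(f"period {period!r}: no variation in lag_days")
        X = sm.add_constant(lag)
        res = sm.OLS(sub[value].to_numpy(dtype=float), X).fit()
        lo, hi = res.conf_int(alpha=0.05)[1]
        out.append(LagCheck(period=period, slope=float(res.params[1]),
                            ci_low=float(lo), ci_high=float(hi), n=len(sub)))
    return out
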
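"""Candidate-model set, AICc ranking, and the fewest-df selection rule.

Six candidate models explain each response (foraging probability,
efficiency, forage quality) within an activity bout:

======================  ====================================================
name                    fixed effects
======================  ====================================================
``daytime3*hunt``       cubic spline of bout hour, separate spline per
                        period, plus a hunting-period intercept shift
``daytime3:hunt``       separate spline per period, common intercept
``daytime3+hunt``       one shared spline plus a hunting intercept shift
``daytime3``            one shared spline only
``hunt``                hunting intercept shift only
``1``                   intercept only
======================  ====================================================

All models carry a bear-id random intercept and are fitted by maximum
likelihood (:mod:`foragerisk.mixed`).  The time effect is an unpenalized
cubic regression-spline basis of fixed dimension ``k`` (default 6) with
knots at quantiles of the observed bout hours — a fixed-df stand-in for
penalized smooths, so every model has a well-defined parameter count for
AICc.  Candidates are ranked by AICc; the *selected* model is the one with
the fewest degrees of freedom among all models within 2 AICc units of the
best (ties on df broken by smaller AICc).

Bout hours: the day splits at the activity minimum (default 10:00) into a
morning bout running 22:00 -> 10:00 and an afternoon bout 10:00 -> 22:00;
each is mapped onto a continuous 0-12 h axis (morning crosses midnight:
22:00 -> 0, 10:00 -> 12) so the spline sees an unbroken time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .mixed import MixedFit, fit_mixed

__all__ = [
    "CANDIDATE_NAMES",
    "SplineBasis",
    "CandidateFit",
    "spline_basis",
    "bout_axis_hour",
    "candidate_design",
    "aicc",
    "rank_and_select",
    "run_candidate_set",
]

CANDIDATE_NAMES = (
    "daytime3*hunt",
    "daytime3:hunt",
    "daytime3+hunt",
    "daytime3",
    "hunt",
    "1",
)

_DEGREE = 3


@dataclass(frozen=True)
class SplineBasis:
    """A cubic B-spline basis: knot vector, dimension, design matrix."""

    knots: np.ndarray
    k: int
    design: np.ndarray = field(repr=False)

    def evaluate(self, hours) -> np.ndarray:
        return _eval_basis(np.asarray(hours, dtype=float), self.knots)


def _eval_basis(x, knots):
    lo, hi = knots[_DEGREE], knots[-_DEGREE - 1]
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, _DEGREE, extrapolate=False).toarray()


def spline_basis(hours, k: int = 6) -> SplineBasis:
    """Cubic regression-spline basis with ``k`` functions.

    Interior knots sit at quantiles of the observed hours; boundary knots
    at the observed range.  The constant function lies in the span (the
    basis functions sum to one), so designs built from it include the
    intercept via the usual drop-one-column convention.
    """
    hours = np.asarray(hours, dtype=float)
    distinct = np.unique(hours)
    if k < 4:
        raise ValueError("cubic spline basis needs k >= 4")
    if distinct.size < k:
        raise ValueError(
            f"only {distinct.size} distinct hours for a k={k} basis; use a smaller k"
        )
    n_interior = k - _DEGREE - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(distinct, qs) if n_interior else np.empty(0)
    lo, hi = distinct.min(), distinct.max()
    knots = np.r_[[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)]
    return SplineBasis(knots=knots, k=k, design=_eval_basis(hours, knots))


def bout_axis_hour(hour_of_day, bout: str, split_hour: float = 10.0) -> np.ndarray:
    """Map clock hours onto the bout's continuous 0-12 axis.

    Afternoon: ``hour - split``.  Morning: hours from ``split + 12``
    (previous evening) onward, crossing midnight, so 22:00 -> 0 and
    10:00 -> 12 with the default split.
    """
    h = np.asarray(hour_of_day, dtype=float)
    if bout == "afternoon":
        return (h - split_hour) % 24.0
    if bout == "morning":
        return (h - split_hour - 12.0) % 24.0
    raise ValueError(f"unknown bout {bout!r}")


def candidate_design(
    name: str, hours, hunt, basis: SplineBasis | None = None, k: int = 6
) -> tuple[np.ndarray, list[str], SplineBasis | None]:
    """Fixed-effects design matrix for one candidate model.

    ``hours`` are bout-axis hours; ``hunt`` is the 0/1 hunting-period
    indicator.  Spline models drop the first basis column against the
    explicit intercept (the constant is in the basis span).
    """
    hunt = np.asarray(hunt, dtype=float)
    ones = np.ones(len(hunt))
    if name == "1":
        return ones[:, None], ["intercept"], None
    if name == "hunt":
        return np.column_stack([ones, hunt]), ["intercept", "hunt"], None
    if basis is None:
        basis = spline_basis(hours, k=k)
    B = basis.design[:, 1:]  # drop-one for identifiability with intercept
    bnames = [f"s{j}" for j in range(1, B.shape[1] + 1)]
    if name == "daytime3":
        X = np.column_stack([ones, B])
        return X, ["intercept", *bnames], basis
    if name == "daytime3+hunt":
        X = np.column_stack([ones, hunt, B])
        return X, ["intercept", "hunt", *bnames], basis
    if name == "daytime3:hunt":
        X = np.column_stack([ones, B * (1.0 - hunt)[:, None], B * hunt[:, None]])
        names = ["intercept", *[f"{b}:pre" for b in bnames], *[f"{b}:hunt" for b in bnames]]
        return X, names, basis
    if name == "daytime3*hunt":
        X = np.column_stack([ones, hunt, B, B * hunt[:, None]])
        names = ["intercept", "hunt", *bnames, *[f"{b}:hunt" for b in bnames]]
        return X, names, basis
    raise ValueError(f"unknown candidate model {name!r}")


def aicc(loglik: float, df: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logLik + 2 df + 2 df (df+1)/(n-df-1)."""
    if n <= df + 1:
        raise ValueError(f"AICc undefined: n = {n} <= df + 1 = {df + 1}")
    return -2.0 * loglik + 2.0 * df + 2.0 * df * (df + 1.0) / (n - df - 1.0)


@dataclass(frozen=True)
class CandidateFit:
    """One fitted candidate with its AICc bookkeeping."""

    name: str
    response: str
    bout: str
    fit: MixedFit | None
    df: int
    n: int
    loglik: float
    aicc: float
    status: str = "ok"


def rank_and_select(fits: list[CandidateFit], delta_max: float = 2.0):
    """Rank candidates by AICc and apply the fewest-df-within-delta rule.

    Returns ``(table, selected_name)``.  The table carries deltaAICc and
    Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2) over the
    successfully fitted candidates; failed fits keep their status and get
    no weight.  The selected model has the fewest df among candidates with
    deltaAICc <= ``delta_max`` (ties broken by smaller AICc).
    """
    if not fits:
        raise ValueError("no candidate fits supplied")
    ok = [f for f in fits if f.status == "ok"]
    if not ok:
        raise ValueError("no candidate converged; nothing to rank")
    ns = {f.n for f in ok}
    if len(ns) > 1:
        raise ValueError(f"candidates fitted to different n: {sorted(ns)} (not comparable)")
    best = min(f.aicc for f in ok)
    deltas = {f.name: f.aicc - best for f in ok}
    rel = {name: np.exp(-d / 2.0) for name, d in deltas.items()}
    total = sum(rel.values())
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.name,
                "df": f.df,
                "logLik": f.loglik if f.status == "ok" else np.nan,
                "AICc": f.aicc if f.status == "ok" else np.nan,
                "deltaAICc": deltas.get(f.name, np.nan),
                "weight": rel[f.name] / total if f.name in rel else np.nan,
                "status": f.status,
            }
        )
    table = pd.DataFrame(rows)
    contenders = [f for f in ok if deltas[f.name] <= delta_max]
    selected = min(contenders, key=lambda f: (f.df, f.aicc))
    return table, selected.name


def run_candidate_set(
    data: pd.DataFrame,
    response: str,
    bout: str,
    family: str,
    k: int = 6,
    n_quad: int = 9,
    split_hour: float = 10.0,
) -> tuple[pd.DataFrame, str]:
    """Fit all six candidates for one response in one bout and rank them.

    ``data`` needs columns ``hour`` (clock hour-of-day, fractional),
    ``hunt`` (0/1), ``animal_id``, and the response column.  Rows are
    restricted to the requested bout before fitting.  A candidate whose
    fit fails is kept in the output with a failure status rather than
    aborting the set.
    """
    for col in ("hour", "hunt", "animal_id", response):
        if col not in data.columns:
            raise ValueError(f"data missing column {col!r}")
    h = np.asarray(data["hour"], dtype=float)
    axis = bout_axis_hour(h, bout, split_hour)
    in_bout = axis < 12.0
    sub = data.loc[in_bout]
    axis = axis[in_bout]
    y = sub[response].to_numpy(dtype=float)
    hunt = sub["hunt"].to_numpy(dtype=float)
    groups = sub["animal_id"].to_numpy()
    n = len(sub)

    basis = spline_basis(axis, k=k)
    fits: list[CandidateFit] = []
    for name in CANDIDATE_NAMES:
        try:
            X, _, _ = candidate_design(name, axis, hunt, basis=basis, k=k)
            mf = fit_mixed(y, X, groups, family=family, n_quad=n_quad)
            fits.append(
                CandidateFit(name, response, bout, mf, mf.df, n, mf.loglik,
                             aicc(mf.loglik, mf.df, n))
            )
        except Exception as exc:  # keep the set alive; record the failure
            df_guess = X.shape[1] + (1 if family == "binomial" else 2)
            fits.append(
                CandidateFit(name, response, bout, None, df_guess, n,
                             np.nan, np.nan, status=f"failed: {exc}")
            )
    table, selected = rank_and_select([f for f in fits])
    table.insert(0, "bout", bout)
    table.insert(0, "response", response)
    return table, selected
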
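"""Average marginal effects and the stressor-range sensitivity sweep.

AMEs are reported in outcome percentage points per unit of the covariate,
averaged over the estimation sample, with delta-method standard errors from
the fit's robust covariance. Continuous effects use the chain rule through
any interaction terms the covariate enters; region dummies use the discrete
counterfactual contrast against the reference region. Interaction columns
themselves carry no AME row (their contribution is folded into the
parents), matching the usual reporting convention for interacted models.

The sensitivity sweep predicts the outcome with every covariate held at its
sample mean while one stressor moves between two sample percentiles
(default 5th and 95th), interaction products recomputed consistently.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import INTERCEPT, interaction_parents
from .models import FitResult, inv_logit


def _model_meta(fit: FitResult):
    m = fit.model
    if m is None:
        raise ValueError("fit carries no model/design information")
    return m.X, list(m.column_names), list(getattr(m, "region_block", []))


def _interactions_of(column_names: list[str], var: str) -> list[tuple[int, str]]:
    out = []
    for j, name in enumerate(column_names):
        parents = interaction_parents(name)
        if parents and var in parents:
            partner = parents[1] if parents[0] == var else parents[0]
            out.append((j, partner))
    return out


def _mean_response_beta(fit: FitResult, X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Family mean response at an arbitrary coefficient vector (sigma fixed
    at its estimate for Tobit)."""
    saved = fit.params
    try:
        fit.params = beta
        return fit.model.mean_response(X, fit)
    finally:
        fit.params = saved


def _numeric_beta_gradient(func, beta: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(beta)
    for j in range(len(beta)):
        step = h * max(1.0, abs(beta[j]))
        bp, bm = beta.copy(), beta.copy()
        bp[j] += step
        bm[j] -= step
        g[j] = (func(bp) - func(bm)) / (2 * step)
    return g


# ---------------------------------------------------------------------------
# continuous AME
# ---------------------------------------------------------------------------

def ame_continuous(fit: FitResult, var: str) -> tuple[float, float]:
    """AME of a continuous covariate, in percentage points per unit.

    (1/n) sum_i dE[y|x_i]/dx_var, with the derivative including every
    interaction the covariate enters; delta-method SE from the robust
    covariance.
    """
    X, names, region_block = _model_meta(fit)
    if var not in names:
        raise KeyError(f"{var!r} is not a model column")
    j_var = names.index(var)
    if j_var in region_block:
        raise ValueError(f"{var!r} is a region dummy; use ame_discrete")
    if interaction_parents(var):
        raise ValueError(
            f"{var!r} is an interaction column; AMEs are reported for its parents"
        )
    inters = _interactions_of(names, var)
    beta = fit.params
    n = X.shape[0]

    # chain-rule coefficient per observation
    def chain(beta_):
        c = np.full(n, beta_[j_var])
        for j_int, partner in inters:
            c = c + beta_[j_int] * X[:, names.index(partner)]
        return c

    if fit.family == "fractional_logit":
        mu = inv_logit(X @ beta)
        g = mu * (1 - mu)
        ame = float(np.mean(g * chain(beta))) * 100.0
        # analytic gradient of the AME in beta
        gprime = g * (1 - 2 * mu)  # d/deta mu(1-mu)
        c = chain(beta)
        grad = (X * (gprime * c)[:, None]).mean(axis=0)
        grad[j_var] += float(np.mean(g))
        for j_int, partner in inters:
            grad[j_int] += float(np.mean(g * X[:, names.index(partner)]))
        grad = grad * 100.0
    elif fit.family == "ols":
        ame = float(np.mean(chain(beta))) * 100.0
        grad = np.zeros_like(beta)
        grad[j_var] = 1.0
        for j_int, partner in inters:
            grad[j_int] = float(np.mean(X[:, names.index(partner)]))
        grad = grad * 100.0
    else:  # tobit and any other smooth family: numeric delta gradient
        def ame_of(beta_):
            h = 1e-6
            Xp, Xm = X.copy(), X.copy()
            Xp[:, j_var] += h
            Xm[:, j_var] -= h
            for j_int, partner in inters:
                Xp[:, j_int] = Xp[:, j_var] * Xp[:, names.index(partner)]
                Xm[:, j_int] = Xm[:, j_var] * Xm[:, names.index(partner)]
            diff = _mean_response_beta(fit, Xp, beta_) - _mean_response_beta(fit, Xm, beta_)
            return float(np.mean(diff) / (2 * h)) * 100.0

        ame = ame_of(beta)
        grad = _numeric_beta_gradient(ame_of, beta)

    se = float(np.sqrt(max(grad @ fit.cov_robust @ grad, 0.0)))
    return ame, se


# ---------------------------------------------------------------------------
# discrete (region dummy) AME
# ---------------------------------------------------------------------------

def ame_discrete(fit: FitResult, dummy_var: str) -> tuple[float, float]:
    """Discrete AME of a region dummy against the reference region, in
    percentage points: the averaged counterfactual contrast between setting
    this dummy to 1 (all others 0) and the all-dummies-zero reference."""
    X, names, region_block = _model_meta(fit)
    if dummy_var not in names:
        raise KeyError(f"{dummy_var!r} is not a model column")
    j = names.index(dummy_var)
    if region_block and j not in region_block:
        raise ValueError(f"{dummy_var!r} is not a region dummy; use ame_continuous")
    X1, X0 = X.copy(), X.copy()
    for k in region_block or [j]:
        X1[:, k] = 0.0
        X0[:, k] = 0.0
    X1[:, j] = 1.0
    beta = fit.params

    if fit.family == "fractional_logit":
        mu1, mu0 = inv_logit(X1 @ beta), inv_logit(X0 @ beta)
        ame = float(np.mean(mu1 - mu0)) * 100.0
        g1, g0 = mu1 * (1 - mu1), mu0 * (1 - mu0)
        grad = (X1 * g1[:, None] - X0 * g0[:, None]).mean(axis=0) * 100.0
    else:
        def ame_of(beta_):
            diff = _mean_response_beta(fit, X1, beta_) - _mean_response_beta(fit, X0, beta_)
            return float(np.mean(diff)) * 100.0

        ame = ame_of(beta)
        grad = _numeric_beta_gradient(ame_of, beta)

    se = float(np.sqrt(max(grad @ fit.cov_robust @ grad, 0.0)))
    return ame, se


# ---------------------------------------------------------------------------
# effects table
# ---------------------------------------------------------------------------

def effects_table(fit: FitResult) -> pd.DataFrame:
    """AMEs for every main effect and region dummy of a fitted model.

    Interaction columns and the intercept are omitted; their influence is
    carried by the parent variables' chain-rule derivatives.
    """
    _, names, region_block = _model_meta(fit)
    rows = []
    for j, name in enumerate(names):
        if name == INTERCEPT or interaction_parents(name):
            continue
        if j in region_block:
            ame, se = ame_discrete(fit, name)
            kind = "discrete-dummy"
        else:
            ame, se = ame_continuous(fit, name)
            kind = "continuous"
        rows.append({"variable": name, "ame": ame, "se": se, "kind": kind})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# percentile sensitivity sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepEntry:
    variable: str
    value_lo: float
    value_hi: float
    pred_lo: float  # outcome %, all other covariates at sample means
    pred_hi: float
    se_lo: float
    se_hi: float

    @property
    def response_range(self) -> float:
        return self.pred_hi - self.pred_lo


def percentile_sweep(
    fit: FitResult, var: str, p_lo: float = 5.0, p_hi: float = 95.0
) -> SweepEntry:
    """Predicted outcome (in %) with ``var`` at its p_lo/p_hi sample
    percentiles and every other covariate at its sample mean; interaction
    products involving ``var`` are recomputed consistently. SEs are
    delta-method SEs of each predicted mean."""
    X, names, region_block = _model_meta(fit)
    if var not in names:
        raise KeyError(f"{var!r} is not a model column")
    j_var = names.index(var)
    col = X[:, j_var]
    lo, hi = (float(np.percentile(col, q)) for q in (p_lo, p_hi))
    if lo == hi:
        warnings.warn(f"{var!r} has a zero-width percentile range", UserWarning)
    inters = _interactions_of(names, var)

    base = X.mean(axis=0)

    def at(value: float) -> np.ndarray:
        x = base.copy()
        x[j_var] = value
        for j_int, partner in inters:
            x[j_int] = value * base[names.index(partner)]
        return x

    out = {}
    for tag, value in (("lo", lo), ("hi", hi)):
        x = at(value)
        if fit.family == "fractional_logit":
            mu = float(inv_logit(x @ fit.params))
            grad = mu * (1 - mu) * x * 100.0
            pred = mu * 100.0
        else:
            def pred_of(beta_, x=x):
                return float(_mean_response_beta(fit, x[None, :], beta_)[0]) * 100.0

            pred = pred_of(fit.params)
            grad = _numeric_beta_gradient(pred_of, fit.params)
        se = float(np.sqrt(max(grad @ fit.cov_robust @ grad, 0.0)))
        out[tag] = (pred, se)
    return SweepEntry(
        variable=var,
        value_lo=lo,
        value_hi=hi,
        pred_lo=out["lo"][0],
        pred_hi=out["hi"][0],
        se_lo=out["lo"][1],
        se_hi=out["hi"][1],
    )


def sweep_table(fit: FitResult, variables: list[str] | None = None,
                p_lo: float = 5.0, p_hi: float = 95.0) -> pd.DataFrame:
    """Percentile sweep for several stressors, as a plotting-ready table."""
    _, names, region_block = _model_meta(fit)
    if variables is None:
        variables = [
            n for j, n in enumerate(names)
            if n != INTERCEPT and j not in region_block and not interaction_parents(n)
        ]
    entries = [percentile_sweep(fit, v, p_lo, p_hi) for v in variables]
    return pd.DataFrame(
        {
            "variable": [e.variable for e in entries],
            "value_p_lo": [e.value_lo for e in entries],
            "value_p_hi": [e.value_hi for e in entries],
            "pred_p_lo": [e.pred_lo for e in entries],
            "pred_p_hi": [e.pred_hi for e in entries],
            "se_p_lo": [e.se_lo for e in entries],
            "se_p_hi": [e.se_hi for e in entries],
        }
    )


def effect_ratio(sweep: pd.DataFrame, var_a: str, var_b: str) -> float:
    """|response range of var_a| / |response range of var_b| from a sweep table."""
    ranges = {}
    for v in (var_a, var_b):
        row = sweep[sweep["variable"] == v]
        if row.empty:
            raise KeyError(f"{v!r} not in sweep table")
        ranges[v] = abs(float(row["pred_p_hi"].iloc[0] - row["pred_p_lo"].iloc[0]))
    if ranges[var_b] == 0.0:
        warnings.warn(f"{var_b!r} has zero response range; ratio is infinite", UserWarning)
        return float("inf")
    return ranges[var_a] / ranges[var_b]
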
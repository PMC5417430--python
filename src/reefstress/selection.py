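"""Repeated k-fold cross-validation for model-family and formula selection.

Each repeat draws a fresh seeded random partition of the sample into k
near-equal folds; every fold serves once as the held-out test set for a
model trained on the remaining k-1 folds. Squared prediction errors are
accumulated on the percent (0-100) scale, matching how the outcome is
reported, and the cross-validated MSE is the grand mean over all held-out
predictions and repeats. Predictive R^2 is 1 - MSE_cv / var(y).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .assembly import ModelSpec, build_design
from .design import INTERCEPT, DesignMatrix
from .models import fit_family

logger = logging.getLogger(__name__)


@dataclass
class CVReport:
    model_id: str
    family: str
    mse: float  # percentage-point^2 scale
    rmse: float
    cv_r2: float
    n_repeats: int
    k: int
    seed: int
    n_obs: int
    n_params: int
    dropped_column_events: int = 0

    def __post_init__(self) -> None:
        assert self.mse >= 0 and abs(self.rmse - np.sqrt(self.mse)) < 1e-9
        assert self.cv_r2 <= 1.0 + 1e-12


def _fold_assignments(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition of range(n) into k near-equal folds (sizes differ by
    at most one)."""
    idx = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(idx, k)):
        folds[chunk] = f
    return folds


def _constant_columns(dm: DesignMatrix) -> list[str]:
    out = []
    for j, name in enumerate(dm.column_names):
        if name == INTERCEPT:
            continue
        col = dm.X[:, j]
        if np.all(col == col[0]):
            out.append(name)
    return out


def kfold_cv(
    dm: DesignMatrix,
    family: str = "fractional_logit",
    k: int = 10,
    n_repeats: int = 1000,
    seed: int = 0,
    model_id: str | None = None,
) -> CVReport:
    """Repeated k-fold cross-validated prediction error for one model.

    Folds that leave a dummy column constant in the training split (making
    the design rank deficient) are refit with the offending column dropped;
    its coefficient is implicitly zero for the held-out predictions and the
    event is counted and logged.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = dm.n_obs
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} observations, got {n}")
    rng = np.random.default_rng(seed)
    sq_errors: list[np.ndarray] = []
    dropped_events = 0
    y_pct = dm.y * 100.0
    for _ in range(n_repeats):
        folds = _fold_assignments(n, k, rng)
        for f in range(k):
            test = folds == f
            train_dm = dm.subset(~test)
            dead = _constant_columns(train_dm)
            test_dm = dm.subset(test)
            if dead:
                dropped_events += 1
                logger.info(
                    "fold %d: dropping constant column(s) %s before refit", f, dead
                )
                train_dm = train_dm.drop_columns(dead)
                test_dm = test_dm.drop_columns(dead)
            fit = fit_family(train_dm, family)
            with warnings.catch_warnings():
                # OLS legitimately predicts outside [0,1]; no need to flag
                # every held-out fold
                warnings.simplefilter("ignore", UserWarning)
                pred_pct = fit.predict(test_dm.X) * 100.0
            sq_errors.append((y_pct[test] - pred_pct) ** 2)
    mse = float(np.mean(np.concatenate(sq_errors)))
    var_y = float(np.var(y_pct))
    return CVReport(
        model_id=model_id or dm.spec_name or family,
        family=family,
        mse=mse,
        rmse=float(np.sqrt(mse)),
        cv_r2=1.0 - mse / var_y if var_y > 0 else (1.0 if mse == 0 else -np.inf),
        n_repeats=n_repeats,
        k=k,
        seed=seed,
        n_obs=n,
        n_params=dm.n_params,
        dropped_column_events=dropped_events,
    )


def compare_models(
    rows,
    candidates: list[ModelSpec],
    families: list[str] = ("fractional_logit", "tobit", "ols"),
    k: int = 10,
    n_repeats: int = 20,
    seed: int = 0,
    region_col: str = "region",
) -> list[CVReport]:
    """CV every (candidate spec, family) pair on the same data and rank by
    MSE ascending, ties broken in favour of fewer parameters.

    ``rows`` may be a prebuilt DesignMatrix (single candidate) or the
    analysis DataFrame from which each candidate's design is built.
    """
    reports: list[CVReport] = []
    for spec in candidates:
        dm = rows if isinstance(rows, DesignMatrix) else build_design(rows, spec, region_col)
        for family in families:
            reports.append(
                kfold_cv(
                    dm,
                    family=family,
                    k=k,
                    n_repeats=n_repeats,
                    seed=seed,
                    model_id=f"{spec.name}:{family}",
                )
            )
    reports.sort(key=lambda r: (r.mse, r.n_params))
    return reports
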
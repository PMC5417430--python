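"""Published reference estimates from the 2005 Caribbean mass-bleaching
event analysis.

These are the fitted fractional-logit coefficient and average-marginal-
effect tables for the mortality and bleaching models of that event
(robust SEs in parentheses in the original tables), shipped as package
data for worked examples and for arithmetic consistency checks — e.g. the
mortality AME of maximum DHW, 0.492 percentage points per °C-week, implies
about a 4.9-point mortality increase per 10 DHW. They are *reported
values*, not something this package recomputes: the underlying survey data
were never publicly deposited.
"""
from __future__ import annotations

import pandas as pd

_MORTALITY_ROWS = [
    # variable, coef, coef_se, ame, ame_se
    ("max_dhw", 0.304, 0.050, 0.492, 0.071),
    ("max_par_anomaly", -0.0073, 0.015, 0.0808, 0.018),
    ("pop_density", 0.0373, 0.031, 0.0679, 0.057),
    ("wind", 0.00114, 0.040, 0.00207, 0.073),
    ("depth", -0.143, 0.056, -0.0969, 0.023),
    ("depth:max_par_anomaly", 0.00517, 0.0012, None, None),
    ("depth:max_dhw", -0.00328, 0.0040, None, None),
    ("region[Bermuda]", -10.9, 0.46, -93.1, 5.8),
    ("region[Bahamian]", 1.56, 0.77, -6.2, 3.5),
    ("region[Eastern Caribbean]", 0.474, 0.35, -4.7, 1.6),
    ("region[Greater Antilles]", 0.896, 0.42, 4.9, 2.3),
    ("region[Southern Caribbean]", -2.08, 1.03, -7.4, 2.6),
    ("region[Southwestern Caribbean]", -0.380, 0.35, -19.5, 2.2),
    ("region[Floridian]", -1.23, 0.47, -12.3, 2.2),
    ("const", -5.74, 0.89, None, None),
]

_BLEACHING_ROWS = [
    ("obs_dhw", 0.201, 0.014, 3.31, 0.16),
    ("max_par_anomaly", 0.0268, 0.0054, -0.0274, 0.059),
    ("dfs", -0.0363, 0.0137, -0.72, 0.27),
    ("pop_density", 0.0311, 0.0059, 0.618, 0.12),
    ("wind", 0.0132, 0.0085, 0.263, 0.17),
    ("depth", 0.0734, 0.011, 0.375, 0.085),
    ("depth:obs_dhw", -0.00336, 0.0010, None, None),
    ("depth:max_par_anomaly", -0.00246, 0.00049, None, None),
    ("region[Bermuda]", 0.114, 0.137, -19.8, 1.7),
    ("region[Bahamian]", 1.05, 0.245, 2.8, 1.4),
    ("region[Eastern Caribbean]", 0.0185, 0.156, 0.86, 0.64),
    ("region[Greater Antilles]", 0.325, 0.188, 1.6, 0.77),
    ("region[Southern Caribbean]", 1.16, 0.148, -3.8, 1.9),
    ("region[Southwestern Caribbean]", 0.605, 0.148, -0.69, 0.63),
    ("region[Floridian]", 0.476, 0.176, -2.2, 0.89),
    ("const", -2.421, 0.198, None, None),
]

MORTALITY_FIT_STATS = {
    "loglik": -64.3,
    "cv_mse": 430.64,
    "cv_rmse": 5.53,
    "cv_r2": 0.325,
    "n_obs": 1045,
}

BLEACHING_FIT_STATS = {
    "loglik": -1299.0,
    "cv_mse": 607.0,
    "cv_rmse": 24.6,
    "cv_r2": 0.29,
    "n_obs": 2945,
}


def _table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["variable", "coef", "coef_se", "ame", "ame_se"])


def mortality_reference() -> pd.DataFrame:
    """Reference mortality-model estimates (coefficients and AMEs)."""
    return _table(_MORTALITY_ROWS)


def bleaching_reference() -> pd.DataFrame:
    """Reference bleaching-model estimates (coefficients and AMEs)."""
    return _table(_BLEACHING_ROWS)


def ame_per_units(table: pd.DataFrame, variable: str, units: float = 10.0) -> float:
    """Outcome change (percentage points) implied by a ``units``-sized move
    of ``variable``, from a reference AME column."""
    row = table[table["variable"] == variable]
    if row.empty or pd.isna(row["ame"].iloc[0]):
        raise KeyError(f"no AME reported for {variable!r}")
    return float(row["ame"].iloc[0]) * units
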
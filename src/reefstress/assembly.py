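"""Build the analysis table: composite outcomes, thermal-stress inclusion
filter, ecoregion lumping and design-matrix construction.

Observation tables are pandas DataFrames with one row per survey
measurement. Outcomes arrive as percentages of area cover and of colonies
affected; the analysis response is the average of the two (they are treated
as interchangeable measurements of the same quantity), stored in percent
and converted to a fraction only when a design matrix is built.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import INTERCEPT, DesignMatrix, interaction_name
from .exceptions import SchemaError

DEFAULT_GRACE_DAYS = 90
DEFAULT_MIN_REGION_OBS = 10

# canonical observation-table columns
OUTCOME_PAIRS = {
    "bleaching": ("cover_bleached", "colonies_bleached"),
    "mortality": ("cover_dead", "colonies_dead"),
}


# ---------------------------------------------------------------------------
# outcome scale: the single place percent <-> fraction conversion happens
# ---------------------------------------------------------------------------

def percent_to_fraction(pct):
    """Convert an outcome on the reporting scale (0-100 %) to a fraction."""
    return np.asarray(pct, dtype=float) / 100.0


def fraction_to_percent(frac):
    """Convert a model-scale fraction back to the reporting scale (0-100 %)."""
    return np.asarray(frac, dtype=float) * 100.0


# ---------------------------------------------------------------------------
# composite outcomes
# ---------------------------------------------------------------------------

def composite_outcome(cover: float | None, colonies: float | None) -> float:
    """Average of the area-based and colony-based percentage measurements.

    Either argument may be missing (None/NaN); the composite is then the
    present value. Both missing -> NaN, flagging the row for exclusion.
    """
    vals = [
        float(v)
        for v in (cover, colonies)
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    for v in vals:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"outcome percentage out of [0, 100]: {v}")
    if not vals:
        return float("nan")
    return float(sum(vals) / len(vals))


def add_composite_outcomes(obs: pd.DataFrame) -> pd.DataFrame:
    """Add 'bleaching'/'mortality' composite percent columns where the parent
    measurement columns exist."""
    out = obs.copy()
    for name, (cover_col, col_col) in OUTCOME_PAIRS.items():
        if cover_col in out.columns or col_col in out.columns:
            cover = out.get(cover_col, pd.Series(np.nan, index=out.index)).astype(float)
            colonies = out.get(col_col, pd.Series(np.nan, index=out.index)).astype(float)
            bad = pd.concat([cover, colonies], axis=1).stack()
            if ((bad < 0) | (bad > 100)).any():
                raise ValueError(f"{name} outcome percentages out of [0, 100]")
            out[name] = pd.concat([cover, colonies], axis=1).mean(axis=1, skipna=True)
    return out


# ---------------------------------------------------------------------------
# thermal-stress-window inclusion filter
# ---------------------------------------------------------------------------

def thermal_window_filter(
    obs: pd.DataFrame,
    alerts: pd.DataFrame,
    warning_level: int = 1,
    no_stress_level: int = 0,
    grace_days: int = DEFAULT_GRACE_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep observations attributable to thermal stress.

    A record is retained when first_warning_date <= obs_date <=
    last_no_stress_date + grace_days, with dates compared at day resolution
    and inclusive boundaries. ``alerts`` has columns (site_id, date, level);
    a warning is any level >= ``warning_level`` and a no-stress alert is
    level == ``no_stress_level``.

    Returns (kept rows, exclusion log) where the log has columns
    (site_id, obs_date, reason).
    """
    for col in ("site_id", "obs_date"):
        if col not in obs.columns:
            raise SchemaError(col)
    for col in ("site_id", "date", "level"):
        if col not in alerts.columns:
            raise SchemaError(col)

    alerts = alerts.copy()
    alerts["date"] = pd.to_datetime(alerts["date"]).dt.normalize()
    obs_dates = pd.to_datetime(obs["obs_date"]).dt.normalize()

    first_warning = (
        alerts[alerts["level"] >= warning_level].groupby("site_id")["date"].min()
    )
    last_no_stress = (
        alerts[alerts["level"] == no_stress_level].groupby("site_id")["date"].max()
    )

    keep = np.zeros(len(obs), dtype=bool)
    reasons: list[str | None] = [None] * len(obs)
    sites_with_alerts = set(alerts["site_id"])
    for i, (site, d) in enumerate(zip(obs["site_id"], obs_dates)):
        if site not in sites_with_alerts:
            reasons[i] = "no_alert_data"
        elif site not in first_warning.index:
            reasons[i] = "no_warning_issued"
        elif d < first_warning[site]:
            reasons[i] = "before_first_warning"
        elif site in last_no_stress.index and d > last_no_stress[site] + pd.Timedelta(days=grace_days):
            reasons[i] = "after_grace_window"
        else:
            keep[i] = True

    log = pd.DataFrame(
        {
            "site_id": obs["site_id"][~keep].to_numpy(),
            "obs_date": obs_dates[~keep].to_numpy(),
            "reason": [r for r in reasons if r is not None],
        }
    )
    return obs[keep].copy(), log


# ---------------------------------------------------------------------------
# region lumping
# ---------------------------------------------------------------------------

def lump_regions(
    obs: pd.DataFrame,
    min_obs: int = DEFAULT_MIN_REGION_OBS,
    merge_map: Mapping[str, str] | None = None,
    region_col: str = "region",
) -> dict[str, str]:
    """Map each ecoregion label to its analysis region.

    Regions with fewer than ``min_obs`` observations merge into a neighbour:
    the explicitly supplied ``merge_map`` target if given, else the region
    with nearest observation centroid (requires lon/lat columns), else the
    most-observed region. The merged unit is labelled "target / small".
    Regions at or above the threshold map to themselves.
    """
    if region_col not in obs.columns:
        raise SchemaError(region_col)
    counts = obs[region_col].value_counts()
    mapping = {r: r for r in counts.index}
    small = [r for r in counts.index if counts[r] < min_obs]
    big = [r for r in counts.index if counts[r] >= min_obs]
    if not big:
        return mapping
    have_geo = {"lon", "lat"}.issubset(obs.columns)
    centroids = (
        obs.groupby(region_col)[["lon", "lat"]].mean() if have_geo else None
    )
    for r in small:
        if merge_map and r in merge_map:
            target = merge_map[r]
        elif centroids is not None:
            d2 = (
                (centroids.loc[big, "lon"] - centroids.loc[r, "lon"]) ** 2
                + (centroids.loc[big, "lat"] - centroids.loc[r, "lat"]) ** 2
            )
            target = d2.idxmin()
        else:
            target = counts.loc[big].idxmax()
        joint = f"{target} / {r}"
        mapping[r] = joint
        mapping[target] = joint
    return mapping


def apply_region_mapping(
    obs: pd.DataFrame, mapping: Mapping[str, str], region_col: str = "region"
) -> pd.DataFrame:
    out = obs.copy()
    out[region_col] = out[region_col].map(lambda r: mapping.get(r, r))
    return out


# ---------------------------------------------------------------------------
# model specifications and design construction
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Which response, main effects and interactions enter one model."""

    name: str
    response: str
    main_effects: list[str]
    interactions: list[tuple[str, str]] = field(default_factory=list)


#: mortality: maximum (worst since season start) thermal and radiative stress
MORTALITY_SPEC = ModelSpec(
    name="mortality",
    response="mortality",
    main_effects=["max_dhw", "max_par_anomaly", "pop_density", "wind", "depth"],
    interactions=[("depth", "max_par_anomaly"), ("depth", "max_dhw")],
)

#: bleaching: near-term (observed) thermal stress plus distance from shore
BLEACHING_SPEC = ModelSpec(
    name="bleaching",
    response="bleaching",
    main_effects=["obs_dhw", "max_par_anomaly", "dfs", "pop_density", "wind", "depth"],
    interactions=[("depth", "obs_dhw"), ("depth", "max_par_anomaly")],
)


def build_design(
    rows: pd.DataFrame,
    spec: ModelSpec,
    region_col: str = "region",
    reference_region: str | None = None,
) -> DesignMatrix:
    """Assemble intercept + main effects + interaction products + k-1 region
    dummies into a DesignMatrix, converting the percent response to a
    fraction.

    The reference (dropped) region defaults to the most-observed region,
    preferring a lumped joint region if one exists. Rows with a missing
    response are dropped.
    """
    missing = [c for c in [spec.response] + spec.main_effects if c not in rows.columns]
    if missing:
        raise SchemaError(", ".join(missing))

    rows = rows[rows[spec.response].notna()].reset_index(drop=True)
    y = percent_to_fraction(rows[spec.response].to_numpy())

    names: list[str] = [INTERCEPT]
    cols: list[np.ndarray] = [np.ones(len(rows))]
    for var in spec.main_effects:
        names.append(var)
        cols.append(rows[var].to_numpy(dtype=float))
    for a, b in spec.interactions:
        for parent in (a, b):
            if parent not in rows.columns:
                raise SchemaError(parent)
        names.append(interaction_name(a, b))
        cols.append(rows[a].to_numpy(dtype=float) * rows[b].to_numpy(dtype=float))

    region_block: list[int] = []
    if region_col in rows.columns and rows[region_col].nunique() > 1:
        counts = rows[region_col].value_counts()
        if reference_region is None:
            joint = [r for r in counts.index if " / " in str(r)]
            reference_region = joint[0] if joint else counts.idxmax()
        for r in sorted(set(rows[region_col]) - {reference_region}):
            region_block.append(len(names))
            names.append(f"region[{r}]")
            cols.append((rows[region_col] == r).to_numpy(dtype=float))

    return DesignMatrix(
        X=np.column_stack(cols),
        y=y,
        column_names=names,
        region_block=region_block,
        response_name=spec.response,
        spec_name=spec.name,
    )
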
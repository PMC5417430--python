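"""Accumulated and instantaneous stressor metrics for coral observations.

The thermal metric is degree heating weeks (DHW): the sum of weekly
sea-surface-temperature anomalies of at least 1 °C above the maximum
climatological monthly mean (MMM), accumulated over a 12-week window.
The radiative analogue accumulates weekly photosynthetically active
radiation (PAR) in excess of a climatological maximum baseline. Each
accumulated metric comes in two flavours: *observed* (the window ending on
the observation date) and *maximum* (the worst window since the start of
the warm season), with maximum >= observed by construction.

Instantaneous / static covariates: running maximum wind speed before the
observation date, maximum population density within a radius of the site,
and great-circle distance from shore.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CoverageError, MissingDataError, WindowLengthError
from .geo import haversine_km, point_segments_km, polyline_segments

DHW_WINDOW_WEEKS = 12
DHW_ANOMALY_THRESHOLD_C = 1.0  # anomalies below this are rounded to zero
DEFAULT_SEASON_START = date(2005, 1, 1)
DEFAULT_POP_RADIUS_KM = 50.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SiteGeo:
    """Location, depth and ecoregion membership of a survey site."""

    site_id: str
    lon: float
    lat: float
    depth: float
    region_label: str = ""

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon out of range: {self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range: {self.lat}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")


@dataclass
class StressorSeries:
    """Per-site weekly environmental series with climatological baselines.

    ``week_start_dates`` must be strictly increasing with uniform 7-day
    spacing; ``sst_weekly`` and ``par_weekly`` share that index. Wind and
    thermal-alert series carry their own (date, value) cadence.
    """

    site_id: str
    week_start_dates: Sequence[date]
    sst_weekly: np.ndarray
    mmm_sst: float
    par_weekly: np.ndarray | None = None
    par_clim_monthly_max: float | None = None
    wind_dates: Sequence[date] = field(default_factory=list)
    wind_values: np.ndarray = field(default_factory=lambda: np.array([]))
    alert_dates: Sequence[date] = field(default_factory=list)
    alert_levels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.week_start_dates = [pd.Timestamp(d).date() for d in self.week_start_dates]
        self.sst_weekly = np.asarray(self.sst_weekly, dtype=float)
        if self.par_weekly is not None:
            self.par_weekly = np.asarray(self.par_weekly, dtype=float)
        deltas = {
            (b - a).days for a, b in zip(self.week_start_dates[:-1], self.week_start_dates[1:])
        }
        if deltas and deltas != {7}:
            raise ValueError("week_start_dates must be strictly increasing with 7-day spacing")
        if len(self.sst_weekly) != len(self.week_start_dates):
            raise ValueError("sst_weekly length must match week_start_dates")
        if self.par_weekly is not None and len(self.par_weekly) != len(self.week_start_dates):
            raise ValueError("par_weekly length must match week_start_dates")


@dataclass
class StressorVector:
    """All stressor covariates matched to one observation."""

    observed_dhw: float
    maximum_dhw: float
    observed_par_anomaly: float
    maximum_par_anomaly: float
    par_12wk_mean: float
    max_wind: float
    pop_density: float
    dfs: float

    def __post_init__(self) -> None:
        if self.maximum_dhw < self.observed_dhw - 1e-12:
            raise ValueError("maximum_dhw must be >= observed_dhw")
        if self.maximum_par_anomaly < self.observed_par_anomaly - 1e-12:
            raise ValueError("maximum_par_anomaly must be >= observed_par_anomaly")
        for name in ("observed_dhw", "observed_par_anomaly", "max_wind", "pop_density", "dfs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# windowed accumulation metrics
# ---------------------------------------------------------------------------

def _check_window(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) != DHW_WINDOW_WEEKS:
        raise WindowLengthError(
            f"{what} window must contain exactly {DHW_WINDOW_WEEKS} weekly values, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise MissingDataError(f"{what} window contains missing/non-finite values")
    return values


def degree_heating_weeks(weekly_sst: Sequence[float], mmm: float) -> float:
    """DHW (°C-weeks) over one 12-week window.

    Sums weekly anomalies ``sst - mmm``; anomalies below 1 °C are treated as
    non-anomalous and contribute zero, anomalies >= 1 °C contribute their full
    value.
    """
    sst = _check_window(np.asarray(weekly_sst), "SST")
    if not np.isfinite(mmm):
        raise MissingDataError("MMM baseline is not finite")
    anom = sst - float(mmm)
    return float(np.sum(np.where(anom >= DHW_ANOMALY_THRESHOLD_C, anom, 0.0)))


def par_anomaly(weekly_par: Sequence[float], clim_max: float) -> float:
    """Accumulated PAR anomaly (Einstein/m²·day) over one 12-week window.

    Positive excess of each weekly PAR value over the climatological maximum
    baseline; zero indicates no radiative stress.
    """
    par = _check_window(np.asarray(weekly_par), "PAR")
    if not np.isfinite(clim_max):
        raise MissingDataError("PAR climatological baseline is not finite")
    excess = par - float(clim_max)
    return float(np.sum(np.where(excess > 0.0, excess, 0.0)))


def par_12wk_mean(weekly_par: Sequence[float]) -> float:
    """Arithmetic mean of 12 weekly PAR values (the 'raw' PAR formulation)."""
    par = _check_window(np.asarray(weekly_par), "PAR")
    return float(np.mean(par))


def _window_indices(
    week_starts: Sequence[date], obs_date: date, season_start: date
) -> tuple[int, list[int]]:
    """Return (index of observed window end, candidate end indices for maximum).

    A window of 12 weeks "ends at" index ``i`` when it spans
    ``week_starts[i-11] .. week_starts[i]``. Candidate windows lie entirely
    within [season_start, obs_date].
    """
    obs_date = pd.Timestamp(obs_date).date()
    season_start = pd.Timestamp(season_start).date()
    ends_le_obs = [i for i, d in enumerate(week_starts) if d <= obs_date]
    if not ends_le_obs:
        raise CoverageError(f"no weekly data on or before observation date {obs_date}")
    obs_end = ends_le_obs[-1]
    if obs_end < DHW_WINDOW_WEEKS - 1:
        raise CoverageError(
            f"fewer than {DHW_WINDOW_WEEKS} weeks of data before observation date {obs_date}"
        )
    candidates = [
        i
        for i in range(DHW_WINDOW_WEEKS - 1, obs_end + 1)
        if week_starts[i - DHW_WINDOW_WEEKS + 1] >= season_start
    ]
    if obs_end not in candidates:
        raise CoverageError(
            f"observed 12-week window extends before season start {season_start}"
        )
    return obs_end, candidates


def observed_and_max_dhw(
    series: StressorSeries, obs_date: date, season_start: date = DEFAULT_SEASON_START
) -> tuple[float, float]:
    """(observed DHW, maximum DHW) in °C-weeks for one observation date.

    Observed: the 12-week window ending on the observation date. Maximum: the
    highest DHW over all 12-week windows lying within
    [season_start, obs_date]; by construction maximum >= observed.
    """
    obs_end, candidates = _window_indices(series.week_start_dates, obs_date, season_start)
    dhw_at = lambda i: degree_heating_weeks(
        series.sst_weekly[i - DHW_WINDOW_WEEKS + 1 : i + 1], series.mmm_sst
    )
    observed = dhw_at(obs_end)
    maximum = max(dhw_at(i) for i in candidates)
    return observed, maximum


def observed_and_max_par_anomaly(
    series: StressorSeries, obs_date: date, season_start: date = DEFAULT_SEASON_START
) -> tuple[float, float]:
    """(observed, maximum) accumulated PAR anomaly, mirroring the DHW dual form."""
    if series.par_weekly is None or series.par_clim_monthly_max is None:
        raise MissingDataError(f"site {series.site_id} has no PAR series/baseline")
    obs_end, candidates = _window_indices(series.week_start_dates, obs_date, season_start)
    pa_at = lambda i: par_anomaly(
        series.par_weekly[i - DHW_WINDOW_WEEKS + 1 : i + 1], series.par_clim_monthly_max
    )
    observed = pa_at(obs_end)
    maximum = max(pa_at(i) for i in candidates)
    return observed, maximum


def observed_par_12wk_mean(series: StressorSeries, obs_date: date) -> float:
    """Mean PAR over the 12 weeks ending at the observation date."""
    if series.par_weekly is None:
        raise MissingDataError(f"site {series.site_id} has no PAR series")
    obs_end, _ = _window_indices(
        series.week_start_dates, obs_date, series.week_start_dates[0]
    )
    return par_12wk_mean(series.par_weekly[obs_end - DHW_WINDOW_WEEKS + 1 : obs_end + 1])


# ---------------------------------------------------------------------------
# instantaneous / static covariates
# ---------------------------------------------------------------------------

def max_wind_before(
    wind_dates: Sequence[date],
    wind_values: Sequence[float],
    obs_date: date,
    season_start: date = DEFAULT_SEASON_START,
) -> float:
    """Maximum wind speed (m/s) recorded in [season_start, obs_date]."""
    obs_date = pd.Timestamp(obs_date).date()
    season_start = pd.Timestamp(season_start).date()
    values = np.asarray(wind_values, dtype=float)
    dates = [pd.Timestamp(d).date() for d in wind_dates]
    mask = np.array([season_start <= d <= obs_date for d in dates], dtype=bool)
    if not mask.any():
        raise CoverageError(f"no wind data in [{season_start}, {obs_date}]")
    sel = values[mask]
    if not np.all(np.isfinite(sel)):
        raise MissingDataError("wind series contains missing values in the query window")
    return float(np.max(sel))


def pop_density_within_radius(
    site: SiteGeo,
    grid_lons: np.ndarray,
    grid_lats: np.ndarray,
    grid_density: np.ndarray,
    radius_km: float = DEFAULT_POP_RADIUS_KM,
) -> float:
    """Maximum population density (1000 people/km²) within ``radius_km`` of a site.

    The grid is given by 1-D coordinate vectors and a (lat, lon) density
    array; a cell belongs to the disc when its center lies within the
    great-circle radius.
    """
    grid_lons = np.asarray(grid_lons, dtype=float)
    grid_lats = np.asarray(grid_lats, dtype=float)
    grid_density = np.asarray(grid_density, dtype=float)
    if grid_density.shape != (len(grid_lats), len(grid_lons)):
        raise ValueError("grid_density must have shape (n_lat, n_lon)")
    lon2, lat2 = np.meshgrid(grid_lons, grid_lats)
    dist = haversine_km(site.lon, site.lat, lon2, lat2)
    within = dist <= radius_km
    if not within.any():
        raise CoverageError(
            f"no population grid cells within {radius_km} km of site {site.site_id}"
        )
    return float(np.nanmax(grid_density[within]))


def distance_from_shore(site: SiteGeo, coastlines: Sequence[np.ndarray]) -> float:
    """Minimum great-circle distance (km) from a site to any coastline polyline."""
    if len(coastlines) == 0:
        raise CoverageError("no coastline geometry supplied")
    seg_a, seg_b = zip(*(polyline_segments(poly) for poly in coastlines))
    return float(
        np.min(point_segments_km(site.lon, site.lat, np.vstack(seg_a), np.vstack(seg_b)))
    )


# ---------------------------------------------------------------------------
# observation matching
# ---------------------------------------------------------------------------

def stressors_for_observation(
    series: StressorSeries,
    site: SiteGeo,
    obs_date: date,
    grid_lons: np.ndarray,
    grid_lats: np.ndarray,
    grid_density: np.ndarray,
    coastlines: Sequence[np.ndarray],
    season_start: date = DEFAULT_SEASON_START,
    pop_radius_km: float = DEFAULT_POP_RADIUS_KM,
) -> StressorVector:
    """Assemble the full stressor covariate vector for one observation."""
    obs_dhw, max_dhw = observed_and_max_dhw(series, obs_date, season_start)
    obs_pa, max_pa = observed_and_max_par_anomaly(series, obs_date, season_start)
    return StressorVector(
        observed_dhw=obs_dhw,
        maximum_dhw=max_dhw,
        observed_par_anomaly=obs_pa,
        maximum_par_anomaly=max_pa,
        par_12wk_mean=observed_par_12wk_mean(series, obs_date),
        max_wind=max_wind_before(series.wind_dates, series.wind_values, obs_date, season_start),
        pop_density=pop_density_within_radius(
            site, grid_lons, grid_lats, grid_density, pop_radius_km
        ),
        dfs=distance_from_shore(site, coastlines),
    )
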
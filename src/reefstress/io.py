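"""Plain-text (CSV/JSON) readers and writers for every pipeline artefact.

Site-matched environmental series travel as long-format CSV
(site_id, date, value); the population grid as (lon, lat, density) rows;
the coastline as ordered (segment, lon, lat) vertices. These are the same
files the ``reefstress simulate`` command writes, so simulated and user
data enter the pipeline identically.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stressors import StressorSeries
from .synthdata import Environment


def read_observations(path) -> pd.DataFrame:
    obs = pd.read_csv(path, parse_dates=["obs_date"])
    return obs


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False)


def _write_long(df_wide: dict, dates, path, value_name: str) -> None:
    rows = []
    for sid, values in df_wide.items():
        rows.append(pd.DataFrame({"site_id": sid, "date": dates, value_name: values}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_environment(env: Environment, out_dir) -> dict[str, Path]:
    """Write a simulated campaign's inputs as CSV files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    sites = env.sites.copy()
    paths["sites"] = out / "sites.csv"
    sites.to_csv(paths["sites"], index=False)

    any_series = next(iter(env.series.values()))
    dates = pd.to_datetime(any_series.week_start_dates)
    paths["sst"] = out / "sst_weekly.csv"
    _write_long({s.site_id: s.sst_weekly for s in env.series.values()}, dates, paths["sst"], "sst")
    paths["par"] = out / "par_weekly.csv"
    _write_long({s.site_id: s.par_weekly for s in env.series.values()}, dates, paths["par"], "par")
    paths["wind"] = out / "wind_weekly.csv"
    _write_long({s.site_id: s.wind_values for s in env.series.values()}, dates, paths["wind"], "wind")

    paths["baselines"] = out / "baselines.csv"
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in env.series.values()],
            "mmm_sst": [s.mmm_sst for s in env.series.values()],
            "par_clim_monthly_max": [s.par_clim_monthly_max for s in env.series.values()],
        }
    ).to_csv(paths["baselines"], index=False)

    paths["alerts"] = out / "alerts.csv"
    env.alerts.to_csv(paths["alerts"], index=False)

    paths["pop"] = out / "population_grid.csv"
    glon, glat = np.meshgrid(env.pop_lons, env.pop_lats)
    pd.DataFrame(
        {"lon": glon.ravel(), "lat": glat.ravel(), "density": env.pop_density.ravel()}
    ).to_csv(paths["pop"], index=False)

    paths["coast"] = out / "coastline.csv"
    rows = []
    for k, poly in enumerate(env.coastlines):
        for lon, lat in poly:
            rows.append({"segment": k, "lon": lon, "lat": lat})
    pd.DataFrame(rows).to_csv(paths["coast"], index=False)
    return paths


def read_environment(in_dir) -> Environment:
    """Read the CSV artefacts written by :func:`write_environment`."""
    d = Path(in_dir)
    sites = pd.read_csv(d / "sites.csv", parse_dates=["obs_date"])
    sst = pd.read_csv(d / "sst_weekly.csv", parse_dates=["date"])
    par = pd.read_csv(d / "par_weekly.csv", parse_dates=["date"])
    wind = pd.read_csv(d / "wind_weekly.csv", parse_dates=["date"])
    baselines = pd.read_csv(d / "baselines.csv").set_index("site_id")
    alerts = pd.read_csv(d / "alerts.csv", parse_dates=["date"])

    series = {}
    for sid, grp in sst.groupby("site_id"):
        grp = grp.sort_values("date")
        pgrp = par[par["site_id"] == sid].sort_values("date")
        wgrp = wind[wind["site_id"] == sid].sort_values("date")
        agrp = alerts[alerts["site_id"] == sid].sort_values("date")
        series[sid] = StressorSeries(
            site_id=sid,
            week_start_dates=list(grp["date"].dt.date),
            sst_weekly=grp["sst"].to_numpy(),
            mmm_sst=float(baselines.loc[sid, "mmm_sst"]),
            par_weekly=pgrp["par"].to_numpy(),
            par_clim_monthly_max=float(baselines.loc[sid, "par_clim_monthly_max"]),
            wind_dates=list(wgrp["date"].dt.date),
            wind_values=wgrp["wind"].to_numpy(),
            alert_dates=list(agrp["date"].dt.date),
            alert_levels=agrp["level"].to_numpy(),
        )

    pop = pd.read_csv(d / "population_grid.csv")
    lons = np.sort(pop["lon"].unique())
    lats = np.sort(pop["lat"].unique())
    density = (
        pop.pivot_table(index="lat", columns="lon", values="density")
        .reindex(index=lats, columns=lons)
        .to_numpy()
    )
    coast = pd.read_csv(d / "coastline.csv")
    coastlines = [
        grp[["lon", "lat"]].to_numpy() for _, grp in coast.groupby("segment")
    ]
    return Environment(
        sites=sites,
        series=series,
        alerts=alerts,
        pop_lons=lons,
        pop_lats=lats,
        pop_density=density,
        coastlines=coastlines,
    )


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
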
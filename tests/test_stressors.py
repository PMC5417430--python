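"""Stressor metrics: accumulation rules, dual observed/maximum windows,
spatial covariates, and brute-force oracle equivalence."""
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefstress import geo, stressors
from reefstress.exceptions import CoverageError, MissingDataError, WindowLengthError
from reefstress.stressors import (
    SiteGeo,
    StressorSeries,
    StressorVector,
    degree_heating_weeks,
    distance_from_shore,
    max_wind_before,
    observed_and_max_dhw,
    par_12wk_mean,
    par_anomaly,
    pop_density_within_radius,
)

MMM = 29.0


def weekly_dates(n, start=date(2005, 1, 3)):
    return [start + timedelta(days=7 * i) for i in range(n)]


# ---------------------------------------------------------------------------
# independent explicit-loop oracles
# ---------------------------------------------------------------------------

def dhw_oracle(sst, mmm):
    total = 0.0
    for s in sst:
        a = s - mmm
        if a >= 1.0:
            total += a
    return total


def par_anomaly_oracle(par, clim_max):
    total = 0.0
    for p in par:
        if p > clim_max:
            total += p - clim_max
    return total


def max_wind_oracle(dates, values, start, end):
    best = None
    for d, v in zip(dates, values):
        if start <= d <= end:
            best = v if best is None else max(best, v)
    return best


# ---------------------------------------------------------------------------
# accumulation windows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "anomalies, expected",
    [
        ([0.5] * 12, 0.0),  # all below the 1 degree rounding threshold
        ([2.0] * 12, 24.0),
        ([0.9, 1.5, 3.0] + [0.0] * 9, 4.5),
        ([1.0] * 12, 12.0),  # threshold is inclusive
        ([0.999] * 12, 0.0),
    ],
)
def test_dhw_examples(anomalies, expected):
    sst = [MMM + a for a in anomalies]
    assert degree_heating_weeks(sst, MMM) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "par, clim, expected",
    [
        ([40.0] * 12, 45.0, 0.0),
        ([46.0] * 12, 45.0, 12.0),
        ([47.0, 45.5] + [40.0] * 10, 45.0, 2.5),
    ],
)
def test_par_anomaly_examples(par, clim, expected):
    assert par_anomaly(par, clim) == pytest.approx(expected, abs=1e-12)


def test_par_12wk_mean_examples(rng):
    assert par_12wk_mean([40.0] * 12) == 40.0
    assert par_12wk_mean([30.0] * 6 + [50.0] * 6) == 40.0
    x = rng.uniform(20, 60, 12)
    assert par_12wk_mean(x) == pytest.approx(sum(x) / 12.0, abs=1e-12)


@pytest.mark.parametrize("func, extra", [(degree_heating_weeks, MMM), (par_anomaly, 45.0), (par_12wk_mean, None)])
def test_window_length_and_missing_errors(func, extra):
    args = lambda vals: (vals,) if extra is None else (vals, extra)
    with pytest.raises(WindowLengthError):
        func(*args([30.0] * 11))
    with pytest.raises(WindowLengthError):
        func(*args([30.0] * 13))
    with pytest.raises(MissingDataError):
        func(*args([30.0] * 11 + [np.nan]))


def test_dhw_missing_baseline_error():
    with pytest.raises(MissingDataError):
        degree_heating_weeks([30.0] * 12, np.nan)


# ---------------------------------------------------------------------------
# observed vs maximum windows
# ---------------------------------------------------------------------------

def make_series(sst, start=date(2005, 1, 3), **kw):
    return StressorSeries(
        site_id="s", week_start_dates=weekly_dates(len(sst), start), sst_weekly=sst,
        mmm_sst=MMM, **kw,
    )


def test_monotone_warming_observed_equals_maximum():
    sst = MMM + np.linspace(0.0, 3.0, 30)
    s = make_series(sst)
    obs, mx = observed_and_max_dhw(s, s.week_start_dates[-1])
    assert obs == pytest.approx(mx)


def test_mid_season_spike_maximum_exceeds_observed():
    sst = np.full(40, MMM)
    sst[10:18] = MMM + 2.5  # hot spell, then cooling
    s = make_series(sst)
    obs, mx = observed_and_max_dhw(s, s.week_start_dates[-1])
    assert mx > obs
    # brute force over every 12-week window
    brute = max(dhw_oracle(sst[i - 11 : i + 1], MMM) for i in range(11, 40))
    assert mx == pytest.approx(brute, abs=1e-12)
    assert obs == pytest.approx(dhw_oracle(sst[-12:], MMM), abs=1e-12)


def test_flat_series_gives_zero_zero():
    s = make_series(np.full(20, MMM))
    assert observed_and_max_dhw(s, s.week_start_dates[-1]) == (0.0, 0.0)


def test_observation_before_coverage_errors():
    s = make_series(np.full(20, MMM))
    with pytest.raises(CoverageError):
        observed_and_max_dhw(s, date(2004, 12, 1))
    with pytest.raises(CoverageError):
        observed_and_max_dhw(s, s.week_start_dates[5])  # < 12 weeks available


def test_flat_tail_never_increases_observed_dhw():
    sst = np.full(40, MMM)
    sst[8:16] = MMM + 2.0
    s = make_series(sst)
    obs_vals = [
        observed_and_max_dhw(s, d)[0] for d in s.week_start_dates[20:]
    ]  # dates over the flat-at-baseline tail
    assert all(b <= a + 1e-12 for a, b in zip(obs_vals[:-1], obs_vals[1:]))


# ---------------------------------------------------------------------------
# wind, population, distance from shore
# ---------------------------------------------------------------------------

def test_max_wind_examples():
    dates = weekly_dates(30)
    const = np.full(30, 5.0)
    assert max_wind_before(dates, const, dates[-1]) == 5.0
    gusty = const.copy()
    gusty[10] = 38.0
    assert max_wind_before(dates, gusty, dates[-1]) == 38.0
    # gust after the observation date is excluded
    assert max_wind_before(dates, gusty, dates[9]) == 5.0
    assert max_wind_before(dates, gusty, dates[9]) == pytest.approx(
        max_wind_oracle(dates, gusty, date(2005, 1, 1), dates[9])
    )
    with pytest.raises(CoverageError):
        max_wind_before(dates, const, date(2004, 1, 1))


def test_pop_density_radius():
    site = SiteGeo("s", -70.0, 20.0, 5.0)
    lons = np.arange(-71.0, -69.0, 0.1)
    lats = np.arange(19.0, 21.0, 0.1)
    grid = np.full((len(lats), len(lons)), 0.7)
    assert pop_density_within_radius(site, lons, lats, grid) == pytest.approx(0.7)

    # a hot cell just inside vs just outside the 50 km disc (1 deg lat = 111.2 km)
    for offset_deg, expect_hot in ((49.0 / 111.1949, True), (51.0 / 111.1949, False)):
        grid2 = np.full((len(lats), len(lons)), 0.1)
        i = int(np.argmin(np.abs(lats - (20.0 + offset_deg))))
        j = int(np.argmin(np.abs(lons - (-70.0))))
        # place the hot cell exactly at the intended offset
        lats2 = lats.copy()
        lats2[i] = 20.0 + offset_deg
        grid2[i, j] = 9.9
        val = pop_density_within_radius(site, lons, lats2, grid2)
        assert val == pytest.approx(9.9 if expect_hot else 0.1)

    off_grid = SiteGeo("t", -70.051, 20.049, 5.0)  # ~7 km from nearest cell center
    with pytest.raises(CoverageError):
        pop_density_within_radius(off_grid, lons, lats, grid, radius_km=1.0)


def test_distance_from_shore():
    meridian = np.column_stack([np.zeros(21), np.linspace(-10, 10, 21)])
    on_coast = SiteGeo("a", 0.0, 0.0, 3.0)
    assert distance_from_shore(on_coast, [meridian]) == pytest.approx(0.0, abs=1e-9)
    east = SiteGeo("b", 1.0, 0.0, 3.0)
    expected = geo.haversine_km(1.0, 0.0, 0.0, 0.0)  # one degree of longitude at the equator
    d = distance_from_shore(east, [meridian])
    assert d == pytest.approx(expected, rel=1e-9)
    assert 110.0 < d < 112.0
    near = np.column_stack([np.full(5, 0.5), np.linspace(-1, 1, 5)])
    assert distance_from_shore(east, [meridian, near]) == pytest.approx(
        geo.haversine_km(1.0, 0.0, 0.5, 0.0), rel=1e-6
    )
    with pytest.raises(CoverageError):
        distance_from_shore(east, [])


def test_point_segment_beats_vertices_between_endpoints():
    # point abeam the middle of an arc is closer to the arc than to either end
    d_seg = geo.point_segment_km(0.5, 1.0, 0.0, 0.0, 1.0, 0.0)
    d_ends = min(geo.haversine_km(0.5, 1.0, 0.0, 0.0), geo.haversine_km(0.5, 1.0, 1.0, 0.0))
    assert d_seg < d_ends


# ---------------------------------------------------------------------------
# invariants and oracle equivalence
# ---------------------------------------------------------------------------

@given(st.integers(0, 11), st.floats(0.0, 5.0))
@settings(max_examples=50, derandomize=True, deadline=None)
def test_dhw_monotone_in_each_week(week, bump):
    base = [MMM + 1.2] * 12
    raised = list(base)
    raised[week] += bump
    assert degree_heating_weeks(raised, MMM) >= degree_heating_weeks(base, MMM)
    # a week already past the threshold contributes linearly
    assert degree_heating_weeks(raised, MMM) == pytest.approx(
        degree_heating_weeks(base, MMM) + bump, abs=1e-9
    )


def test_metrics_match_bruteforce_oracles_on_random_series(rng):
    for _ in range(100):
        n = int(rng.integers(15, 45))
        sst = MMM + rng.normal(0.5, 1.2, n)
        par = rng.uniform(35, 60, n)
        clim = float(rng.uniform(44, 55))
        s = make_series(sst, par_weekly=par, par_clim_monthly_max=clim)
        obs_date = s.week_start_dates[int(rng.integers(11, n))]
        obs, mx = observed_and_max_dhw(s, obs_date)
        end = next(i for i, d in enumerate(s.week_start_dates) if d == obs_date)
        assert obs == pytest.approx(dhw_oracle(sst[end - 11 : end + 1], MMM), abs=1e-10)
        assert mx == pytest.approx(
            max(dhw_oracle(sst[i - 11 : i + 1], MMM) for i in range(11, end + 1)), abs=1e-10
        )
        assert mx >= obs - 1e-12
        po, pm = stressors.observed_and_max_par_anomaly(s, obs_date)
        assert po == pytest.approx(par_anomaly_oracle(par[end - 11 : end + 1], clim), abs=1e-10)
        assert pm >= po - 1e-12


def test_stressor_vector_invariants():
    with pytest.raises(ValueError):
        StressorVector(5.0, 4.0, 0.0, 0.0, 40.0, 10.0, 0.1, 1.0)  # max_dhw < obs
    with pytest.raises(ValueError):
        StressorVector(0.0, 0.0, 0.0, 0.0, 40.0, 10.0, 0.1, -1.0)  # negative dfs
    ok = StressorVector(1.0, 2.0, 0.5, 1.0, 40.0, 10.0, 0.1, 5.0)
    assert ok.maximum_dhw >= ok.observed_dhw


def test_site_geo_validation():
    with pytest.raises(ValueError):
        SiteGeo("x", -200.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        SiteGeo("x", 0.0, 0.0, -1.0)


def test_series_requires_uniform_weekly_spacing():
    dates = weekly_dates(12)
    dates[5] += timedelta(days=1)
    with pytest.raises(ValueError):
        StressorSeries("s", dates, np.full(12, MMM), MMM)
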
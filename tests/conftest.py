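"""Shared fixtures: small synthetic worlds and a brute-force indicator oracle.

The oracle recomputes extreme-day counts directly on the raw (un-binned)
daily/sub-daily series with area-weighted pooled percentiles, independent of
the histogram pathway it is used to check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cropclimex import indicators as ind
from cropclimex import preprocess as pp
from cropclimex import synthetic_data as sd


@pytest.fixture(scope="session")
def small_world():
    """30 cells x 16 years: enough for every code path, cheap to build."""
    cfg = sd.SyntheticConfig(n_cells=30, n_years=16, seed=42)
    weather, calendar, truth, yields = sd.generate_dataset(cfg)
    return cfg, weather, calendar, truth, yields


@pytest.fixture(scope="session")
def small_features(small_world):
    cfg, weather, calendar, truth, yields = small_world
    table = ind.compute_indicators(weather, calendar)
    feats = pp.standardize_features(table)
    anom = pp.detrend_yield(yields)
    data = feats.merge(anom[["cell", "year", "anomaly"]], on=["cell", "year"])
    return table, data


def weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Percentile of a weighted sample: smallest value whose cumulative
    weight fraction reaches q/100 (matches the histogram convention)."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cumfrac = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cumfrac, q / 100.0, side="left")])


def precision_cell(values, width: float, origin: float, n_cells: int) -> np.ndarray:
    """Index of the stated precision cell (0.1 degC / 0.001 deficit) a value
    reports as; the counting convention excludes the whole cell containing
    the threshold, so the oracle compares cell indices."""
    idx = np.floor((np.asarray(values, float) - origin) / width).astype(np.int64)
    return np.clip(idx, 0, n_cells - 1)


def brute_force_counts(
    weather, calendar, window_days: int = 90, samples_per_day: int = 24
) -> pd.DataFrame:
    """Extreme-day counts computed on raw series, no histograms.

    Pools each cell's within-season raw sub-daily temperatures and daily
    deficits across years and regimes (weighted by harvested area), takes
    raw percentiles of the pooled sample, and counts day mass strictly
    beyond them per season.
    """
    dpy = int(weather.attrs.get("days_per_year", 365))
    n_days = weather.sizes["time"]
    n_years = n_days // dpy
    cal = calendar.set_index(["cell", "regime"])
    tmin = weather["tmin"].values
    tmax = weather["tmax"].values
    sm = weather["sm"].values

    rows = []
    for cell in np.atleast_1d(weather["cell"].values):
        cell = int(cell)
        deficit = ind.soil_moisture_to_deficit(
            sm[cell], float(sm[cell].min()), float(sm[cell].max())
        )
        regimes = [
            (
                int(cal.loc[(cell, reg)]["harvest_doy"]),
                float(cal.loc[(cell, reg)]["area_frac"]),
            )
            for reg in ("irrigated", "rainfed")
        ]
        valid_years = [
            y
            for y in range(n_years)
            if all(
                y * dpy + h - window_days >= 0
                and y * dpy + h - 365 >= 0
                and y * dpy + h - 1 < n_days
                for h, _ in regimes
            )
        ]
        if len(valid_years) < 2:
            continue

        # pooled raw samples with area weights
        temp_vals, temp_w, def_vals, def_w = [], [], [], []
        per_season = {}
        for h, area in regimes:
            for y in valid_years:
                win = ind.extract_season_window(h, y, window_days, dpy)
                t_sub = ind.interpolate_daily_temperature(
                    tmin[cell, win], tmax[cell, win], samples_per_day
                ).ravel()
                d = deficit[win]
                temp_vals.append(t_sub)
                temp_w.append(np.full(t_sub.size, area / samples_per_day))
                def_vals.append(d)
                def_w.append(np.full(d.size, area))
                per_season.setdefault(y, []).append((area, t_sub, d))
        temp_vals = np.concatenate(temp_vals)
        temp_w = np.concatenate(temp_w)
        def_vals = np.concatenate(def_vals)
        def_w = np.concatenate(def_w)

        thr_hot = precision_cell(
            weighted_percentile(temp_vals, temp_w, 90), 0.1, -20.0, 800
        )
        thr_cold = precision_cell(
            weighted_percentile(temp_vals, temp_w, 10), 0.1, -20.0, 800
        )
        thr_dry = precision_cell(
            weighted_percentile(def_vals, def_w, 90), 0.001, 0.0, 1000
        )
        thr_wet = precision_cell(
            weighted_percentile(def_vals, def_w, 10), 0.001, 0.0, 1000
        )

        for y in valid_years:
            hot = cold = dry = wet = 0.0
            for area, t_sub, d in per_season[y]:
                t_cell = precision_cell(t_sub, 0.1, -20.0, 800)
                d_cell = precision_cell(d, 0.001, 0.0, 1000)
                hot += area * (t_cell > thr_hot).sum() / samples_per_day
                cold += area * (t_cell < thr_cold).sum() / samples_per_day
                dry += area * (d_cell > thr_dry).sum()
                wet += area * (d_cell < thr_wet).sum()
            rows.append(
                {
                    "cell": cell,
                    "year": y,
                    "hot_days": hot,
                    "cold_days": cold,
                    "dry_days": dry,
                    "wet_days": wet,
                }
            )
    return pd.DataFrame(rows)
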
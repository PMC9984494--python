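"""Model-ready features: yield anomalies, standardized indicators, climate bins.

Yield series are de-trended per cell with a centered 5-year moving average
(truncated at the series edges) and expressed as proportional anomalies, so
slow management or technology trends drop out. Climate indicators are turned
into per-cell z-scores: dry- and wet-day counts are square-root transformed
first (they are right-skewed counts), and the four average-condition
variables (mean temperature, mean soil moisture, season and annual
precipitation) are linearly de-trended over years before z-scoring; extreme
day counts are left un-de-trended in the main configuration, with a
sensitivity flag to de-trend them too. Cells are partitioned into 25 climate
bins by nested quintiles: first on climatological growing-season
temperature, then, within each temperature quintile, on climatological
annual precipitation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "EXTREME_FEATURES",
    "AVERAGE_FEATURES",
    "detrend_yield",
    "standardize_features",
    "cell_climatology",
    "assign_climate_bins",
]

EXTREME_FEATURES = ["hot_days", "dry_days", "cold_days", "wet_days"]
AVERAGE_FEATURES = ["mean_temp", "mean_sm", "gs_precip", "annual_precip"]
SQRT_FEATURES = ("dry_days", "wet_days")


def detrend_yield(yields: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Proportional yield anomalies against a centered moving-average baseline.

    anomaly = (yield - moving_avg) / moving_avg, computed per cell over
    years. The first and last ``window // 2`` years use the truncated
    centered window so every year keeps an anomaly. Cells whose yields are
    all zero are excluded (the ratio is undefined); isolated zero baselines
    drop only the affected rows.
    """
    out = []
    for cell, grp in yields.sort_values(["cell", "year"]).groupby("cell"):
        y = grp["yield"].to_numpy(dtype=float)
        if np.all(y == 0):
            warnings.warn(f"cell {cell}: all-zero yields, excluded from anomalies")
            continue
        baseline = (
            pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
        )
        ok = baseline > 0
        res = grp.loc[ok, ["cell", "year", "yield"]].copy()
        res["baseline"] = baseline[ok]
        res["anomaly"] = (y[ok] - baseline[ok]) / baseline[ok]
        out.append(res)
    if not out:
        return pd.DataFrame(columns=["cell", "year", "yield", "baseline", "anomaly"])
    return pd.concat(out, ignore_index=True)


def _zscore(x: np.ndarray) -> np.ndarray:
    # sample (n-1) sd; constant columns map to zeros (the sigma-threshold
    # event coding depends on this convention staying fixed)
    sd = x.std(ddof=1)
    # numerically-constant columns (incl. float residue of an exact OLS
    # de-trend) map to zeros instead of amplified rounding noise
    if not np.isfinite(sd) or sd <= 1e-9 * max(1.0, float(np.abs(x).max())):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _linear_detrend(x: np.ndarray, year: np.ndarray) -> np.ndarray:
    if len(x) < 2 or np.ptp(year) == 0:
        return x - x.mean()
    slope, intercept = np.polyfit(year, x, 1)
    return x - (slope * year + intercept)


def standardize_features(
    indicators: pd.DataFrame,
    detrend_extremes: bool = False,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell z-scored feature columns from the indicator table.

    dry_days and wet_days are square-root transformed before z-scoring; the
    average-condition variables are OLS-de-trended on year first. Pass
    ``detrend_extremes=True`` to also de-trend the extreme-day counts
    (sensitivity configuration). ``features`` restricts the output columns
    (e.g. the extremes-only configuration).
    """
    if features is None:
        features = EXTREME_FEATURES + AVERAGE_FEATURES
    out = []
    for _, grp in indicators.sort_values(["cell", "year"]).groupby("cell"):
        if len(grp) < 3:
            continue
        year = grp["year"].to_numpy(dtype=float)
        res = grp[["cell", "year"]].copy()
        for col in features:
            x = grp[col].to_numpy(dtype=float)
            if col in SQRT_FEATURES:
                x = np.sqrt(x)
            if col in AVERAGE_FEATURES or (
                detrend_extremes and col in EXTREME_FEATURES
            ):
                x = _linear_detrend(x, year)
            res[col] = _zscore(x)
        out.append(res)
    return pd.concat(out, ignore_index=True)


def cell_climatology(indicators: pd.DataFrame) -> pd.DataFrame:
    """All-years mean growing-season temperature and annual precipitation per cell."""
    clim = (
        indicators.groupby("cell")[["mean_temp", "annual_precip"]]
        .mean()
        .reset_index()
        .rename(columns={"mean_temp": "gs_temp"})
    )
    return clim


def _quintile_groups(values: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Quintile label 0..4 per element; ties broken by stable id order."""
    order = np.lexsort((ids, values))
    labels = np.empty(len(values), dtype=int)
    splits = np.array_split(order, 5)
    for q, idx in enumerate(splits):
        labels[idx] = q
    return labels


def assign_climate_bins(climatology: pd.DataFrame) -> pd.DataFrame:
    """Nested 5x5 quintile binning of cells on (gs_temp, annual_precip).

    Within each temperature quintile the precipitation quintiles are
    computed from that quintile's members only. Bin ids run 1..25 as
    5 * temp_quintile + precip_quintile + 1. Requires >= 25 cells.
    """
    if len(climatology) < 25:
        raise ValueError("need at least 25 cells for 5x5 binning")
    cells = climatology["cell"].to_numpy()
    t_q = _quintile_groups(climatology["gs_temp"].to_numpy(float), cells)
    p_q = np.empty_like(t_q)
    for q in range(5):
        mask = t_q == q
        p_q[mask] = _quintile_groups(
            climatology["annual_precip"].to_numpy(float)[mask], cells[mask]
        )
    return pd.DataFrame(
        {
            "cell": cells,
            "temp_quintile": t_q,
            "precip_quintile": p_q,
            "bin": 5 * t_q + p_q + 1,
        }
    )
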
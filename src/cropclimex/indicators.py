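"""Growing-season climate indicators from daily weather and crop calendars.

For each grid cell, crop season and water regime the daily record inside the
pre-harvest window is turned into histograms of sub-daily temperature (sine
interpolation between tmin and tmax) and daily soil-moisture deficit, the
irrigated and rainfed histograms are merged with harvested-area weights, and
extreme-day counts are read off against percentile thresholds of the pooled
all-years distribution of that cell: days above the 90th percentile are hot
(temperature) or dry (deficit), days below the 10th percentile cold or wet.
Seasonal means of temperature and soil moisture and precipitation totals over
the season and over the 365 days preceding harvest complete the indicator
table.

Histogram bins: temperature -20..60 degC at 0.1 degC (800 bins), deficit
0.0..1.0 at 0.001 (1000 bins); half-open [lower, upper) with the final bin
closed, out-of-range values clamped to the terminal bins so total day mass
is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "TEMP_EDGES",
    "DEFICIT_EDGES",
    "SeasonHistogram",
    "interpolate_daily_temperature",
    "soil_moisture_to_deficit",
    "extract_season_window",
    "accumulate_histograms",
    "merge_regimes",
    "percentile_threshold",
    "count_extreme_days",
    "season_means_and_totals",
    "compute_indicators",
]

TEMP_EDGES = np.round(np.arange(-20.0, 60.0 + 1e-9, 0.1), 10)  # 801 edges, 800 bins
DEFICIT_EDGES = np.round(np.arange(0.0, 1.0 + 1e-9, 0.001), 10)  # 1001 edges

_N_TEMP_BINS = len(TEMP_EDGES) - 1
_N_DEF_BINS = len(DEFICIT_EDGES) - 1


@dataclass
class SeasonHistogram:
    """Binned day counts for one (cell, season-year).

    ``temp_counts`` are in day units (sub-daily sample counts divided by
    ``samples_per_day``); ``deficit_counts`` count whole days. Both sum to
    the season length.
    """

    temp_counts: np.ndarray
    deficit_counts: np.ndarray
    cell: int
    year: int
    season_length: int
    samples_per_day: int = 24

    def __post_init__(self) -> None:
        if (self.temp_counts < 0).any() or (self.deficit_counts < 0).any():
            raise ValueError("histogram counts must be non-negative")


def interpolate_daily_temperature(
    tmin: np.ndarray | float, tmax: np.ndarray | float, samples_per_day: int = 24
) -> np.ndarray:
    """Sub-daily temperature samples assuming a sinusoidal diurnal cycle.

    The daily distribution is modelled as mean + amplitude * sin(phase) with
    mean (tmin+tmax)/2 and amplitude (tmax-tmin)/2, sampled at
    ``samples_per_day`` equispaced phases over one full period. Returns an
    array with a trailing sample axis appended to the input shape.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin must not exceed tmax")
    if samples_per_day < 1:
        raise ValueError("samples_per_day must be >= 1")
    phases = 2.0 * np.pi * np.arange(samples_per_day) / samples_per_day
    mean = (tmin + tmax) / 2.0
    amp = (tmax - tmin) / 2.0
    return mean[..., None] + amp[..., None] * np.sin(phases)


def soil_moisture_to_deficit(
    sm: np.ndarray | float, reference_min: float, reference_max: float
) -> np.ndarray:
    """Rescale volumetric soil moisture to a deficit in [0, 1]; larger = drier.

    deficit = (reference_max - sm) / (reference_max - reference_min), so the
    wettest reference day maps to 0 and the driest to 1.
    """
    if not reference_max > reference_min:
        raise ValueError("degenerate reference range")
    return (reference_max - np.asarray(sm, dtype=float)) / (
        reference_max - reference_min
    )


def extract_season_window(
    harvest_doy: int,
    year: int,
    window_days: int = 90,
    days_per_year: int = 365,
) -> np.ndarray:
    """Absolute day indices of the ``window_days``-day window ending at harvest.

    Day 0 is the first day of year 0. The window runs back from the harvest
    day of ``year`` and may reach into the previous calendar year; it raises
    when it would precede the start of the record (callers drop that first
    season).
    """
    if not 1 <= harvest_doy <= days_per_year:
        raise ValueError("harvest_doy outside the year")
    end = year * days_per_year + harvest_doy - 1
    start = end - window_days + 1
    if start < 0:
        raise ValueError("season window precedes the start of the record")
    return np.arange(start, end + 1)


def _temp_bin_index(values: np.ndarray) -> np.ndarray:
    idx = np.floor((values - TEMP_EDGES[0]) / 0.1).astype(np.int64)
    return np.clip(idx, 0, _N_TEMP_BINS - 1)


def _deficit_bin_index(values: np.ndarray) -> np.ndarray:
    idx = np.floor(values / 0.001).astype(np.int64)
    return np.clip(idx, 0, _N_DEF_BINS - 1)


def accumulate_histograms(
    tmin: np.ndarray,
    tmax: np.ndarray,
    deficit: np.ndarray,
    cell: int = 0,
    year: int = 0,
    samples_per_day: int = 24,
) -> SeasonHistogram:
    """Bin one season's daily record into the temperature/deficit histograms.

    ``tmin``/``tmax``/``deficit`` are 1-D arrays over the season's days.
    Sub-daily temperature samples are generated by sine interpolation; each
    sample contributes 1/samples_per_day of a day to its bin.
    """
    tmin = np.asarray(tmin, float)
    season_length = tmin.size
    if samples_per_day > 1:
        samples = interpolate_daily_temperature(tmin, tmax, samples_per_day).ravel()
    else:
        samples = ((np.asarray(tmin, float) + np.asarray(tmax, float)) / 2.0).ravel()
    temp_counts = (
        np.bincount(_temp_bin_index(samples), minlength=_N_TEMP_BINS).astype(float)
        / samples_per_day
    )
    deficit_counts = np.bincount(
        _deficit_bin_index(np.asarray(deficit, float)), minlength=_N_DEF_BINS
    ).astype(float)
    return SeasonHistogram(
        temp_counts, deficit_counts, cell, year, season_length, samples_per_day
    )


def merge_regimes(
    hist_irr: SeasonHistogram,
    hist_rf: SeasonHistogram,
    area_irr: float,
    area_rf: float,
) -> SeasonHistogram:
    """Harvested-area-weighted bin-wise average of the two regime histograms."""
    if abs(area_irr + area_rf - 1.0) > 1e-9:
        raise ValueError("area weights must sum to 1")
    return SeasonHistogram(
        temp_counts=area_irr * hist_irr.temp_counts + area_rf * hist_rf.temp_counts,
        deficit_counts=area_irr * hist_irr.deficit_counts
        + area_rf * hist_rf.deficit_counts,
        cell=hist_irr.cell,
        year=hist_irr.year,
        season_length=hist_irr.season_length,
        samples_per_day=hist_irr.samples_per_day,
    )


def _pooled_counts(
    histograms: Iterable[SeasonHistogram], variable: str
) -> np.ndarray:
    attr = {"temp": "temp_counts", "deficit": "deficit_counts"}[variable]
    counts = [getattr(h, attr) for h in histograms]
    if not counts:
        raise ValueError("empty histogram pool")
    return np.sum(counts, axis=0)


def percentile_threshold(
    histograms: Sequence[SeasonHistogram] | np.ndarray,
    q: float,
    variable: Literal["temp", "deficit"] = "temp",
) -> int:
    """Bin index of the q-th percentile of the pooled all-years distribution.

    The threshold is the first bin at which the cumulative mass fraction
    reaches q/100; it is invariant to the order in which years are pooled.
    """
    if isinstance(histograms, np.ndarray):
        pooled = histograms
    else:
        pooled = _pooled_counts(histograms, variable)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("empty histogram pool")
    cumfrac = np.cumsum(pooled) / total
    return int(np.searchsorted(cumfrac, q / 100.0, side="left"))


def count_extreme_days(
    hist: SeasonHistogram | np.ndarray,
    threshold_bin: int,
    direction: Literal["above", "below"],
    variable: Literal["temp", "deficit"] = "temp",
) -> float:
    """Day mass strictly beyond the threshold bin in the given direction.

    Mass in the threshold bin itself is excluded, treating the upper and
    lower tails symmetrically.
    """
    if isinstance(hist, np.ndarray):
        counts = hist
    else:
        counts = hist.temp_counts if variable == "temp" else hist.deficit_counts
    if direction == "above":
        return float(counts[threshold_bin + 1 :].sum())
    if direction == "below":
        return float(counts[:threshold_bin].sum())
    raise ValueError(f"invalid direction {direction!r}")


def season_means_and_totals(
    tmean: np.ndarray,
    sm: np.ndarray,
    precip: np.ndarray,
    precip_annual: np.ndarray,
) -> tuple[float, float, float, float]:
    """(mean temperature, mean soil moisture, season precip, annual precip).

    ``precip_annual`` must cover the 365 days ending at harvest.
    """
    return (
        float(np.mean(tmean)),
        float(np.mean(sm)),
        float(np.sum(precip)),
        float(np.sum(precip_annual)),
    )


def compute_indicators(
    weather: xr.Dataset,
    calendar: pd.DataFrame,
    window_days: int = 90,
    samples_per_day: int = 24,
    q_upper: float = 90.0,
    q_lower: float = 10.0,
    deficit_reference: Literal["per_cell", "global"] = "per_cell",
    percentile_basis: Literal["subdaily", "daily"] = "subdaily",
) -> pd.DataFrame:
    """Indicator table per (cell, year) from a weather cube and calendar.

    Years whose season window or whose preceding 365-day precipitation
    window would extend before the record start are dropped (in practice the
    first year). Regime histograms are merged with harvested-area weights
    before thresholds and counts are computed; seasonal means and totals are
    the same area-weighted combination of the per-regime values.
    """
    dpy = int(weather.attrs.get("days_per_year", 365))
    n_days = weather.sizes["time"]
    n_years = n_days // dpy
    tmin_all = weather["tmin"].values
    tmax_all = weather["tmax"].values
    tmean_all = weather["tmean"].values
    precip_all = weather["precip"].values
    sm_all = weather["sm"].values

    if percentile_basis == "daily":
        samples_per_day = 1

    if deficit_reference == "global":
        ref_min = float(sm_all.min())
        ref_max = float(sm_all.max())

    cal = calendar.set_index(["cell", "regime"])
    rows = []
    for cell in np.atleast_1d(weather["cell"].values):
        cell = int(cell)
        if deficit_reference == "per_cell":
            ref_min = float(sm_all[cell].min())
            ref_max = float(sm_all[cell].max())
        deficit_cell = soil_moisture_to_deficit(sm_all[cell], ref_min, ref_max)

        regimes = []
        for regime in ("irrigated", "rainfed"):
            entry = cal.loc[(cell, regime)]
            regimes.append((int(entry["harvest_doy"]), float(entry["area_frac"])))

        # years usable for every regime: window and annual precip both inside record
        valid_years = []
        for year in range(n_years):
            ok = True
            for harvest_doy, _ in regimes:
                end = year * dpy + harvest_doy - 1
                if end - window_days + 1 < 0 or end - 364 < 0 or end >= n_days:
                    ok = False
            if ok:
                valid_years.append(year)
        if len(valid_years) < 2:
            continue

        merged: dict[int, SeasonHistogram] = {}
        means: dict[int, np.ndarray] = {}
        for harvest_doy, area in regimes:
            for year in valid_years:
                window = extract_season_window(harvest_doy, year, window_days, dpy)
                hist = accumulate_histograms(
                    tmin_all[cell, window],
                    tmax_all[cell, window],
                    deficit_cell[window],
                    cell=cell,
                    year=year,
                    samples_per_day=samples_per_day,
                )
                annual = np.arange(window[-1] - 364, window[-1] + 1)
                mt, msm, gsp, anp = season_means_and_totals(
                    tmean_all[cell, window],
                    sm_all[cell, window],
                    precip_all[cell, window],
                    precip_all[cell, annual],
                )
                stats = area * np.array([mt, msm, gsp, anp])
                if year in merged:
                    prev = merged[year]
                    merged[year] = SeasonHistogram(
                        prev.temp_counts + area * hist.temp_counts,
                        prev.deficit_counts + area * hist.deficit_counts,
                        cell,
                        year,
                        hist.season_length,
                        hist.samples_per_day,
                    )
                    means[year] = means[year] + stats
                else:
                    merged[year] = SeasonHistogram(
                        area * hist.temp_counts,
                        area * hist.deficit_counts,
                        cell,
                        year,
                        hist.season_length,
                        hist.samples_per_day,
                    )
                    means[year] = stats

        hists = [merged[y] for y in valid_years]
        thr_hot = percentile_threshold(hists, q_upper, "temp")
        thr_cold = percentile_threshold(hists, q_lower, "temp")
        thr_dry = percentile_threshold(hists, q_upper, "deficit")
        thr_wet = percentile_threshold(hists, q_lower, "deficit")

        for year in valid_years:
            h = merged[year]
            mt, msm, gsp, anp = means[year]
            rows.append(
                {
                    "cell": cell,
                    "year": year,
                    "hot_days": count_extreme_days(h, thr_hot, "above", "temp"),
                    "cold_days": count_extreme_days(h, thr_cold, "below", "temp"),
                    "dry_days": count_extreme_days(h, thr_dry, "above", "deficit"),
                    "wet_days": count_extreme_days(h, thr_wet, "below", "deficit"),
                    "mean_temp": mt,
                    "mean_sm": msm,
                    "gs_precip": gsp,
                    "annual_precip": anp,
                }
            )

    return pd.DataFrame(rows)
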
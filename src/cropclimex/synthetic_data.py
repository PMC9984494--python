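"""Synthetic gridded weather, calendars and yields with known effect sizes.

The generator emulates the statistical structure the downstream analysis
assumes: a sinusoidal seasonal temperature cycle with Gaussian daily
anomalies, volumetric soil moisture negatively coupled to the temperature
anomaly through a bivariate normal, an optional logistic-in-time increase in
the probability of compound hot-dry growing seasons, and yields carrying a
multiplicative penalty in compound seasons on top of a slow management trend
and multiplicative noise.

Every random stage draws from its own substream spawned from the master
seed, so weather, event flags, calendars and yield noise can be regenerated
independently and the whole data set is bit-reproducible for a given config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_calendar",
    "generate_truth",
    "generate_weather",
    "generate_yields",
    "generate_dataset",
    "save_weather",
    "load_weather",
]

# substream labels -> spawn index of the master SeedSequence
_STREAMS = {"calendar": 0, "flags": 1, "weather": 2, "yield_noise": 3}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world.

    Temperatures in degC, soil moisture in m3/m3, precipitation in mm/day,
    yields in t/ha. ``hotdry_trend_logodds_per_year`` is the slope of the
    generative logistic model for compound hot-dry seasons (log-odds per
    year, year centered at the series midpoint); ``hotdry_base_prob`` is the
    event probability at the midpoint. ``year_effect_sd`` is the sd of a
    shared annual log-odds shock emulating the spatial coherence of
    extremes: some years are compound-prone almost everywhere, so the
    global event fraction fluctuates strongly between years instead of
    tracking the trend smoothly.

    Flagged seasons are expressed in the weather as a contiguous hot-dry
    spell of ``event_spell_days`` days with daily anomalies shifted by
    ``event_shift_sd`` daily standard deviations (+ for temperature, - for
    soil moisture), placed at a random position inside the pre-harvest
    window: extremes are episodes, not season-long offsets, so they move
    the extreme-day counts much more than the seasonal means.
    ``interannual_anom_scale`` sets slow year-to-year variability of the
    seasonal mean state (a per cell-year mean anomaly of
    scale * daily sd for both temperature and soil moisture,
    independent of the events), without which seasonal means would be
    unrealistically stable at ~sd/sqrt(90).
    """

    n_cells: int = 100
    n_years: int = 30
    days_per_year: int = 365
    season_length_days: int = 90
    base_temp_by_cell: Sequence[float] | None = None
    seasonal_amplitude: float = 8.0
    temp_sd: float = 3.0
    diurnal_range: float = 8.0
    sm_mean: float = 0.30
    sm_sd: float = 0.06
    temp_sm_corr: float = -0.6
    wet_day_prob: float = 0.4
    precip_mean: float = 5.0
    hotdry_trend_logodds_per_year: float = 0.08
    hotdry_base_prob: float = 0.025
    year_effect_sd: float = 1.25
    event_shift_sd: float = 2.5
    event_spell_days: int = 21
    interannual_anom_scale: float = 0.33
    yield_base: float = 4.0
    hotdry_penalty: float = 0.10
    yield_noise_sd: float = 0.03
    management_trend: float = 0.01
    regime_lag_days: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_years <= 0 or self.days_per_year <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_years < 10:
            raise ValueError("n_years must be >= 10 (moving-average de-trending)")
        if not -1.0 <= self.temp_sm_corr <= 0.0:
            raise ValueError("temp_sm_corr must lie in [-1, 0]")
        if not 0.0 <= self.hotdry_penalty < 1.0:
            raise ValueError("hotdry_penalty must lie in [0, 1)")
        if self.season_length_days >= self.days_per_year:
            raise ValueError("season_length_days must be < days_per_year")
        if not 0.0 <= self.hotdry_base_prob < 1.0:
            raise ValueError("hotdry_base_prob must lie in [0, 1)")

    def marginal_trend_logodds_per_year(self) -> float:
        """Population-averaged logistic slope implied by the generative model.

        The shared annual shock makes the generative model a mixed logistic
        regression; a marginal (ordinary) logistic fit to the flags targets
        the conditional slope attenuated by the standard logit-normal
        factor 1/sqrt(1 + c^2 sigma^2), c = 16 sqrt(3) / (15 pi).
        """
        c2 = (16.0 * np.sqrt(3.0) / (15.0 * np.pi)) ** 2
        return self.hotdry_trend_logodds_per_year / float(
            np.sqrt(1.0 + c2 * self.year_effect_sd**2)
        )

    def base_temps(self) -> np.ndarray:
        if self.base_temp_by_cell is not None:
            temps = np.asarray(self.base_temp_by_cell, dtype=float)
            if temps.shape != (self.n_cells,):
                raise ValueError("base_temp_by_cell length must equal n_cells")
            return temps
        # spread climatologies so quintile binning has distinct values
        return np.linspace(12.0, 28.0, self.n_cells)

    def stream(self, name: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[name]])


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent generative state: which (cell, year) seasons are compound hot-dry."""

    is_hot_dry: np.ndarray  # bool, shape (n_cells, n_years)
    event_prob_by_year: np.ndarray  # shape (n_years,)
    logodds_slope_per_year: float

    def frame(self) -> pd.DataFrame:
        n_cells, n_years = self.is_hot_dry.shape
        cells, years = np.meshgrid(np.arange(n_cells), np.arange(n_years), indexing="ij")
        return pd.DataFrame(
            {
                "cell": cells.ravel(),
                "year": years.ravel(),
                "is_hot_dry": self.is_hot_dry.ravel(),
            }
        )


def generate_calendar(config: SyntheticConfig, window_days: int = 90) -> pd.DataFrame:
    """Per-cell planting/harvest days of year and harvested-area weights.

    Irrigated and rainfed regimes share the cell but the rainfed harvest lags
    by ``regime_lag_days``. Cell 0 always harvests early in the year so that
    its pre-harvest window crosses the year boundary, exercising wrap-around
    logic downstream. Area fractions sum to 1 per cell.
    """
    rng = config.stream("calendar")
    harvest_irr = np.empty(config.n_cells, dtype=int)
    harvest_irr[0] = 45
    if config.n_cells > 1:
        harvest_irr[1:] = rng.integers(120, 331, size=config.n_cells - 1)
    area_irr = rng.uniform(0.1, 0.9, size=config.n_cells)

    dpy = config.days_per_year
    rows = []
    for regime, lag, frac in (
        ("irrigated", 0, area_irr),
        ("rainfed", config.regime_lag_days, 1.0 - area_irr),
    ):
        harvest = (harvest_irr - 1 + lag) % dpy + 1
        planting = (harvest - 1 - config.season_length_days) % dpy + 1
        rows.append(
            pd.DataFrame(
                {
                    "cell": np.arange(config.n_cells),
                    "regime": regime,
                    "planting_doy": planting,
                    "harvest_doy": harvest,
                    "area_frac": frac,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Draw compound hot-dry flags from the generative logistic trend model."""
    rng = config.stream("flags")
    years = np.arange(config.n_years, dtype=float)
    centered = years - (config.n_years - 1) / 2.0
    base_logit = _logit(config.hotdry_base_prob)
    eta = config.year_effect_sd * rng.standard_normal(config.n_years)
    logits = base_logit + config.hotdry_trend_logodds_per_year * centered + eta
    probs = 1.0 / (1.0 + np.exp(-logits))
    flags = rng.random((config.n_cells, config.n_years)) < probs[None, :]
    return SyntheticTruth(
        is_hot_dry=flags,
        event_prob_by_year=probs,
        logodds_slope_per_year=config.hotdry_trend_logodds_per_year,
    )


def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    return float(np.log(p / (1.0 - p)))


def _season_bounds(config: SyntheticConfig, calendar: pd.DataFrame) -> np.ndarray:
    """Absolute (start, end) day of each cell-year's joint season window.

    The window runs from ``season_length_days`` before the earliest regime
    harvest to the latest regime harvest, so it covers both regimes'
    pre-harvest windows (clipped at the record start). Shape
    (n_cells, n_years, 2).
    """
    dpy = config.days_per_year
    harvest = calendar.pivot(index="cell", columns="regime", values="harvest_doy")
    bounds = np.empty((config.n_cells, config.n_years, 2), dtype=np.int64)
    for cell in range(config.n_cells):
        h_irr = int(harvest.loc[cell, "irrigated"])
        h_rf = int(harvest.loc[cell, "rainfed"])
        h_lo, h_hi = min(h_irr, h_rf), max(h_irr, h_rf)
        for year in range(config.n_years):
            end = year * dpy + h_hi - 1
            start = max(year * dpy + h_lo - config.season_length_days, 0)
            bounds[cell, year] = (start, end)
    return bounds


def generate_weather(
    config: SyntheticConfig, truth: SyntheticTruth | None = None
) -> xr.Dataset:
    """Daily weather cube with dims (cell, time).

    Variables: tmin/tmax/tmean (degC), precip (mm/day), sm (m3/m3).
    Coordinates: absolute day index ``time``, plus ``year`` and ``doy``.
    Flagged compound seasons (from ``truth``, generated internally when not
    supplied) carry a contiguous hot-dry spell inside the season window; a
    per cell-year mean anomaly adds slow interannual variability on top of
    the iid daily noise.
    """
    if truth is None:
        truth = generate_truth(config)
    rng = config.stream("weather")
    n_cells, n_years, dpy = config.n_cells, config.n_years, config.days_per_year
    n_days = n_years * dpy

    doy = np.tile(np.arange(1, dpy + 1), n_years)
    year = np.repeat(np.arange(n_years), dpy)
    seasonal = config.seasonal_amplitude * np.sin(2.0 * np.pi * (doy - 1) / dpy)

    z_temp = rng.standard_normal((n_cells, n_days))
    z_indep = rng.standard_normal((n_cells, n_days))
    dtr = np.clip(
        config.diurnal_range + rng.standard_normal((n_cells, n_days)), 1.0, None
    )
    precip = (rng.random((n_cells, n_days)) < config.wet_day_prob) * rng.exponential(
        config.precip_mean, size=(n_cells, n_days)
    )
    # interannual mean state (independent for temperature and soil moisture)
    scale = config.interannual_anom_scale
    t_year_anom = scale * config.temp_sd * rng.standard_normal((n_cells, n_years))
    sm_year_anom = scale * config.sm_sd * rng.standard_normal((n_cells, n_years))

    base = config.base_temps()
    tmean = (
        base[:, None]
        + seasonal[None, :]
        + config.temp_sd * z_temp
        + t_year_anom[:, year]
    )
    rho = config.temp_sm_corr
    sm = (
        config.sm_mean
        + config.sm_sd * (rho * z_temp + np.sqrt(1.0 - rho**2) * z_indep)
        + sm_year_anom[:, year]
    )

    if config.event_shift_sd != 0.0 and truth.is_hot_dry.any():
        calendar = generate_calendar(config)
        bounds = _season_bounds(config, calendar)
        spell = min(config.event_spell_days, config.season_length_days)
        for cell, yr in zip(*np.nonzero(truth.is_hot_dry)):
            start_lo, end = bounds[cell, yr]
            start = int(rng.integers(start_lo, max(end - spell + 2, start_lo + 1)))
            stop = min(start + spell, end + 1)
            tmean[cell, start:stop] += config.event_shift_sd * config.temp_sd
            sm[cell, start:stop] -= config.event_shift_sd * config.sm_sd

    tmin = tmean - dtr / 2.0
    tmax = tmean + dtr / 2.0
    sm = np.clip(sm, 0.0, 1.0)

    return xr.Dataset(
        data_vars={
            "tmin": (("cell", "time"), tmin),
            "tmax": (("cell", "time"), tmax),
            "tmean": (("cell", "time"), tmean),
            "precip": (("cell", "time"), precip),
            "sm": (("cell", "time"), sm),
        },
        coords={
            "cell": np.arange(n_cells),
            "time": np.arange(n_days),
            "year": ("time", year),
            "doy": ("time", doy),
        },
        attrs={
            "days_per_year": dpy,
            "n_years": n_years,
            "seed": config.seed,
        },
    )


def generate_yields(
    weather: xr.Dataset, truth: SyntheticTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Annual yields: management trend x compound-event penalty x noise.

    yield = yield_base * (1 + management_trend)^year
                       * (1 - hotdry_penalty * flag) * (1 + noise)
    with iid Gaussian noise of sd ``yield_noise_sd``.
    """
    n_cells = weather.sizes["cell"]
    n_years = int(weather.attrs["n_years"])
    if truth.is_hot_dry.shape != (n_cells, n_years):
        raise ValueError("truth flags do not cover the weather record")
    rng = config.stream("yield_noise")
    noise = rng.normal(0.0, config.yield_noise_sd, size=(n_cells, n_years))
    years = np.arange(n_years)
    trend = config.yield_base * (1.0 + config.management_trend) ** years
    yields = (
        trend[None, :]
        * (1.0 - config.hotdry_penalty * truth.is_hot_dry)
        * (1.0 + noise)
    )
    cells, yy = np.meshgrid(np.arange(n_cells), years, indexing="ij")
    return pd.DataFrame(
        {"cell": cells.ravel(), "year": yy.ravel(), "yield": yields.ravel()}
    )


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[xr.Dataset, pd.DataFrame, SyntheticTruth, pd.DataFrame]:
    """Convenience wrapper: (weather, calendar, truth, yields) for one config."""
    truth = generate_truth(config)
    weather = generate_weather(config, truth)
    calendar = generate_calendar(config)
    yields = generate_yields(weather, truth, config)
    return weather, calendar, truth, yields


def save_weather(weather: xr.Dataset, path: str) -> None:
    """Write the weather cube as NetCDF (classic format, scipy engine)."""
    weather.to_netcdf(path, engine="scipy")


def load_weather(path: str) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy").load()
    ds.close()
    return ds


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
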
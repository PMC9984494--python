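"""Scenario analysis: yield-anomaly response to single and compound extremes.

Impacts are read off the fitted ensembles by partial dependence: the
standardized extreme-day columns are fixed at chosen sigma values (the
features are per-cell z-scores, so sigma units are native), a random sample
of observations supplies all other columns, and the mean model output -
expressed in percent yield anomaly - is the scenario estimate. Per repeat
the partial dependence is averaged over the four folds; the repeat values
form the uncertainty distribution whose 2.5-97.5 percentile range is the
95% confidence interval. Bin-level maps apply the zero rule: an estimate
whose CI straddles zero is mapped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .yield_model import FoldModel, ModelRun

__all__ = [
    "SCENARIO_LEVELS",
    "ScenarioEstimate",
    "scenario_columns",
    "partial_dependence",
    "compound_scenario",
    "map_bin_estimates",
    "scenario_heatmap",
]

# -2.25 .. 2.25 sigma in 0.25 steps: 19 levels, symmetric about 0
SCENARIO_LEVELS = np.round(np.arange(-2.25, 2.25 + 1e-9, 0.25), 10)

_SCENARIO_COLUMNS = {
    "hot_dry": ("hot_days", "dry_days"),
    "cold_wet": ("cold_days", "wet_days"),
    "hot": ("hot_days",),
    "dry": ("dry_days",),
    "cold": ("cold_days",),
    "wet": ("wet_days",),
}


@dataclass
class ScenarioEstimate:
    """Repeat-level distribution of a scenario's mean yield anomaly (%)."""

    kind: str
    level: float
    values: np.ndarray  # one mean anomaly per repeat, %

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.values, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def contains_zero(self) -> bool:
        lo, hi = self.ci
        return lo <= 0.0 <= hi

    @property
    def mapped(self) -> float:
        """Mean estimate, set to zero when the 95% CI contains zero."""
        return 0.0 if self.contains_zero else self.mean


def scenario_columns(kind: str) -> tuple[str, ...]:
    try:
        return _SCENARIO_COLUMNS[kind]
    except KeyError:
        raise ValueError(f"unknown scenario kind {kind!r}") from None


def partial_dependence(
    fold: FoldModel,
    X_background: np.ndarray,
    feature_names: list[str],
    fixed: dict[str, float],
    sample_size: int = 1000,
    rng: np.random.Generator | int = 0,
) -> float:
    """Mean model output (% anomaly) with chosen columns fixed at sigma values.

    Draws min(sample_size, n) background observations without replacement,
    overwrites the fixed columns and averages the model prediction.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = len(X_background)
    if n == 0:
        raise ValueError("empty background matrix")
    take = min(sample_size, n)
    sample = X_background[rng.choice(n, size=take, replace=False)].copy()
    for name, value in fixed.items():
        sample[:, feature_names.index(name)] = value
    return float(fold.predict(sample).mean()) * 100.0


def compound_scenario(
    run: ModelRun,
    data: pd.DataFrame,
    kind: str = "hot_dry",
    level: float = 1.5,
    sample_size: int = 1000,
    seed: int = 0,
) -> ScenarioEstimate:
    """Scenario estimate at a single sigma level across all repeats.

    Per repeat the partial dependence is averaged over the four folds, each
    using its own training rows as background (fresh seeded sample per
    repeat). The repeat values form the reported distribution.
    """
    if run.n_repeats < 1:
        raise ValueError("need at least one fitted repeat")
    cols = scenario_columns(kind)
    fixed = {c: level for c in cols}
    X = data[run.feature_names].to_numpy(dtype=float)
    children = np.random.SeedSequence(seed).spawn(run.n_repeats)
    values = []
    for rep, child in zip(run.repeats, children):
        rng = np.random.default_rng(child)
        pd_folds = [
            partial_dependence(
                fold, X[fold.train_rows], run.feature_names, fixed,
                sample_size=sample_size, rng=rng,
            )
            for fold in rep.folds
        ]
        values.append(float(np.mean(pd_folds)))
    return ScenarioEstimate(kind=kind, level=level, values=np.asarray(values))


def map_bin_estimates(
    estimates: dict[int, ScenarioEstimate],
) -> dict[int, float]:
    """Mapped per-bin values: repeat-mean, zeroed when the 95% CI spans zero.

    Bins without a fitted estimate are simply absent from the result.
    """
    return {b: est.mapped for b, est in estimates.items()}


def scenario_heatmap(
    run: ModelRun,
    data: pd.DataFrame,
    axes: tuple[str, str] = ("hot_days", "dry_days"),
    levels: np.ndarray = SCENARIO_LEVELS,
    sample_size: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean anomaly (%) over the full sigma x sigma scenario grid.

    Rows index the first axis, columns the second, both in ascending sigma.
    Each cell is the mean over repeats of the fold-averaged partial
    dependence with both axis features fixed.
    """
    levels = np.asarray(levels, float)
    i0 = run.feature_names.index(axes[0])
    i1 = run.feature_names.index(axes[1])
    X = data[run.feature_names].to_numpy(dtype=float)
    ll0, ll1 = np.meshgrid(levels, levels, indexing="ij")
    grid = np.stack([ll0.ravel(), ll1.ravel()], axis=1)  # (n_grid, 2)
    n_grid = len(grid)

    children = np.random.SeedSequence(seed).spawn(run.n_repeats)
    acc = np.zeros(n_grid)
    for rep, child in zip(run.repeats, children):
        rng = np.random.default_rng(child)
        for fold in rep.folds:
            bg = X[fold.train_rows]
            take = min(sample_size, len(bg))
            sample = bg[rng.choice(len(bg), size=take, replace=False)]
            # one prediction call over the whole grid: tile the background
            # sample per grid point and overwrite the two axis columns
            tiled = np.repeat(grid, take, axis=0)
            block = np.tile(sample, (n_grid, 1))
            block[:, i0] = tiled[:, 0]
            block[:, i1] = tiled[:, 1]
            preds = fold.predict(block).reshape(n_grid, take)
            acc += preds.mean(axis=1) * 100.0
    acc /= run.n_repeats * 4
    return pd.DataFrame(
        acc.reshape(len(levels), len(levels)), index=levels, columns=levels
    )
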
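"""Year-blocked out-of-sample boosted-tree modelling of yield anomalies.

The fitting protocol: years are randomly split into four groups; for each
fold one group is held out for prediction, one is the early-stopping
evaluation set, and the remaining two train the model, so every year's
prediction comes from a model that never saw that year. Hyperparameters
(subsample fraction, feature fraction, L2 penalty, split-gain penalty) are
drawn by randomized search (5 candidates) and selected by year-disjoint
3-fold cross-validation on the training rows. Boosting uses squared-error
trees (at most 400, depth 3, learning rate 0.1) and stops after 40 rounds
without improvement on the evaluation group. Repeating the whole procedure
with re-randomized splits yields an empirical distribution of any downstream
statistic; skill is summarized as the sign-preserved squared Pearson
correlation between reported and predicted anomalies, optionally aggregated
to area-weighted yearly means. Feature attribution uses TreeSHAP
(additive per-observation Shapley values from the fitted trees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .preprocess import AVERAGE_FEATURES, EXTREME_FEATURES

__all__ = [
    "DEFAULT_FEATURES",
    "HYPERPARAM_BOXES",
    "SplitPlan",
    "FoldModel",
    "RepeatResult",
    "ModelRun",
    "make_split_plan",
    "sample_hyperparameters",
    "tune_hyperparameters",
    "fit_fold",
    "fit_repeat",
    "run_model",
    "explained_variance",
    "attribute_features",
    "shap_contributions",
]

DEFAULT_FEATURES = EXTREME_FEATURES + AVERAGE_FEATURES

# sampled uniformly by the randomized search
HYPERPARAM_BOXES = {
    "subsample": (0.5, 1.0),
    "colsample_bytree": (0.5, 1.0),
    "reg_lambda": (0.5, 1.5),
    "gamma": (0.0, 0.05),
}

_BASE_PARAMS = {
    "max_depth": 3,
    "eta": 0.1,
    "objective": "reg:squarederror",
    "nthread": 1,
    "verbosity": 0,
}


@dataclass(frozen=True)
class SplitPlan:
    """Assignment of years to 4 groups; fold f holds out group f, evaluates
    early stopping on group (f+1) mod 4 and trains on the remaining two."""

    groups: tuple[tuple[int, ...], ...]

    def fold_roles(self, fold: int) -> tuple[list[int], list[int], list[int]]:
        n = len(self.groups)
        held = list(self.groups[fold])
        eval_ = list(self.groups[(fold + 1) % n])
        train: list[int] = []
        for g in range(n):
            if g != fold and g != (fold + 1) % n:
                train.extend(self.groups[g])
        return train, eval_, held


@dataclass
class FoldModel:
    booster: xgb.Booster
    params: dict
    best_iteration: int
    train_years: tuple[int, ...]
    eval_years: tuple[int, ...]
    held_years: tuple[int, ...]
    train_rows: np.ndarray  # row indices into the feature matrix

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.booster.predict(
            xgb.DMatrix(X), iteration_range=(0, self.best_iteration + 1)
        )


@dataclass
class RepeatResult:
    repeat: int
    plan: SplitPlan
    folds: list[FoldModel]
    predictions: pd.DataFrame  # cell, year, pred


@dataclass
class ModelRun:
    feature_names: list[str]
    repeats: list[RepeatResult] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    def prediction_panel(self) -> pd.DataFrame:
        frames = []
        for rep in self.repeats:
            f = rep.predictions.copy()
            f["repeat"] = rep.repeat
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def make_split_plan(
    years: np.ndarray, n_groups: int = 4, seed: int | np.random.Generator = 0
) -> SplitPlan:
    """Randomly split distinct years into ``n_groups`` groups of size +-1."""
    years = np.unique(np.asarray(years))
    if len(years) < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} distinct years")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    perm = rng.permutation(years)
    groups = tuple(tuple(int(y) for y in g) for g in np.array_split(perm, n_groups))
    return SplitPlan(groups=groups)


def sample_hyperparameters(rng: np.random.Generator) -> dict:
    """One uniform draw from the hyperparameter boxes."""
    return {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in HYPERPARAM_BOXES.items()}


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    row_years: np.ndarray,
    n_iter: int = 5,
    rng: np.random.Generator | int = 0,
    n_trees: int = 400,
    patience: int = 40,
) -> dict:
    """Randomized search over the boxes with year-disjoint 3-fold CV (RMSE).

    Ties in CV error keep the first-sampled candidate.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    years = np.unique(row_years)
    if len(years) < 3:
        raise ValueError("training data must span at least 3 years")
    cv_groups = np.array_split(rng.permutation(years), 3)
    candidates = [sample_hyperparameters(rng) for _ in range(n_iter)]
    xgb_seed = int(rng.integers(2**31))

    best_params, best_err = None, np.inf
    for cand in candidates:
        errs = []
        for g in cv_groups:
            val_mask = np.isin(row_years, g)
            booster, best_it = fit_fold(
                X[~val_mask],
                y[~val_mask],
                X[val_mask],
                y[val_mask],
                cand,
                n_trees=n_trees,
                patience=patience,
                seed=xgb_seed,
            )
            pred = booster.predict(
                xgb.DMatrix(X[val_mask]), iteration_range=(0, best_it + 1)
            )
            errs.append(np.sqrt(np.mean((pred - y[val_mask]) ** 2)))
        err = float(np.mean(errs))
        if err < best_err:
            best_err, best_params = err, cand
    return best_params


def fit_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    hyperparams: dict,
    n_trees: int = 400,
    patience: int = 40,
    seed: int = 0,
) -> tuple[xgb.Booster, int]:
    """Boost with early stopping on the evaluation set.

    Training halts after ``patience`` rounds without improvement of the
    evaluation RMSE over the best round so far (capped at ``n_trees``);
    the best-evaluation-round model is the one used for prediction.
    """
    if len(X_train) == 0 or len(X_eval) == 0:
        raise ValueError("empty train or evaluation partition")
    params = dict(_BASE_PARAMS, **hyperparams, seed=int(seed))
    dtrain = xgb.DMatrix(X_train, label=y_train)
    deval = xgb.DMatrix(X_eval, label=y_eval)
    booster = xgb.train(
        params,
        dtrain,
        num_boost_round=n_trees,
        evals=[(deval, "eval")],
        early_stopping_rounds=patience,
        verbose_eval=False,
    )
    return booster, int(booster.best_iteration)


def fit_repeat(
    data: pd.DataFrame,
    feature_names: list[str] | None = None,
    repeat: int = 0,
    seed: int = 0,
    n_trees: int = 400,
    patience: int = 40,
    n_search_iter: int = 5,
    response: str = "anomaly",
) -> RepeatResult:
    """One full split-tune-fit-predict pass over all four folds."""
    feature_names = feature_names or DEFAULT_FEATURES
    rng = np.random.default_rng(seed)
    X = data[feature_names].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    row_years = data["year"].to_numpy()
    plan = make_split_plan(row_years, seed=rng)

    folds, preds = [], []
    for fold in range(4):
        train_y, eval_y, held_y = plan.fold_roles(fold)
        tr = np.isin(row_years, train_y)
        ev = np.isin(row_years, eval_y)
        ho = np.isin(row_years, held_y)
        params = tune_hyperparameters(
            X[tr], y[tr], row_years[tr], n_iter=n_search_iter, rng=rng,
            n_trees=n_trees, patience=patience,
        )
        booster, best_it = fit_fold(
            X[tr], y[tr], X[ev], y[ev], params,
            n_trees=n_trees, patience=patience, seed=int(rng.integers(2**31)),
        )
        fm = FoldModel(
            booster=booster,
            params=params,
            best_iteration=best_it,
            train_years=tuple(train_y),
            eval_years=tuple(eval_y),
            held_years=tuple(held_y),
            train_rows=np.nonzero(tr)[0],
        )
        folds.append(fm)
        p = data.loc[ho, ["cell", "year"]].copy()
        p["pred"] = fm.predict(X[ho])
        preds.append(p)

    return RepeatResult(
        repeat=repeat,
        plan=plan,
        folds=folds,
        predictions=pd.concat(preds, ignore_index=True),
    )


def run_model(
    data: pd.DataFrame,
    n_repeats: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
    n_trees: int = 400,
    patience: int = 40,
    n_search_iter: int = 5,
    response: str = "anomaly",
) -> ModelRun:
    """Repeat the full protocol ``n_repeats`` times with re-randomized splits."""
    feature_names = feature_names or DEFAULT_FEATURES
    children = np.random.SeedSequence(seed).spawn(n_repeats)
    run = ModelRun(feature_names=list(feature_names))
    for r, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        run.repeats.append(
            fit_repeat(
                data,
                feature_names=feature_names,
                repeat=r,
                seed=rep_seed,
                n_trees=n_trees,
                patience=patience,
                n_search_iter=n_search_iter,
                response=response,
            )
        )
    return run


def explained_variance(
    reported: np.ndarray,
    predicted: np.ndarray,
    years: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    aggregation: str = "global",
) -> float:
    """Sign-preserved squared Pearson correlation between panels.

    ``aggregation="global"`` first aggregates both panels to area-weighted
    yearly means (requires ``years``); ``aggregation="none"`` correlates the
    raw cell-year observations.
    """
    reported = np.asarray(reported, float)
    predicted = np.asarray(predicted, float)
    if aggregation == "global":
        if years is None:
            raise ValueError("years required for global aggregation")
        w = np.ones_like(reported) if weights is None else np.asarray(weights, float)
        df = pd.DataFrame({"year": years, "r": reported * w, "p": predicted * w, "w": w})
        agg = df.groupby("year").sum()
        a = (agg["r"] / agg["w"]).to_numpy()
        b = (agg["p"] / agg["w"]).to_numpy()
    elif aggregation == "none":
        a, b = reported, predicted
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if len(a) < 3:
        raise ValueError("need at least 3 aggregate points")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.sign(r) * r**2)


def shap_contributions(fold: FoldModel, X: np.ndarray) -> np.ndarray:
    """Per-observation TreeSHAP values (last column is the base value).

    Rows satisfy sum(contributions) + base == model prediction.
    """
    return fold.booster.predict(
        xgb.DMatrix(X),
        pred_contribs=True,
        iteration_range=(0, fold.best_iteration + 1),
    )


def attribute_features(
    run: ModelRun, data: pd.DataFrame, max_rows: int = 2000, seed: int = 0
) -> pd.Series:
    """Mean absolute Shapley attribution per feature across all repeats/folds."""
    rng = np.random.default_rng(seed)
    X = data[run.feature_names].to_numpy(dtype=float)
    if len(X) > max_rows:
        X = X[rng.choice(len(X), max_rows, replace=False)]
    total = np.zeros(len(run.feature_names))
    n = 0
    for rep in run.repeats:
        for fold in rep.folds:
            contrib = shap_contributions(fold, X)
            total += np.abs(contrib[:, :-1]).mean(axis=0)
            n += 1
    return pd.Series(total / n, index=run.feature_names, name="mean_abs_shap")
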
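"""Environmental extraction and boosted-regression-tree models of calling.

The BRT follows the classic ecology recipe: stagewise stochastic gradient
boosting of shallow trees (tree complexity 2, learning rate 0.005, bag
fraction 0.75), with the tree count chosen by 10-fold cross-validation on
held-out deviance, cross-validated percent deviance explained (cv_dev) and
correlation (cv_cor), gain-based relative influence normalized to 100%,
and fixed-at-mean partial-dependence curves. The tree ensemble itself is
fit with LightGBM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from scipy import stats
from sklearn.model_selection import KFold

from .propagation import haversine_km
from .synth import EnvGridSeries

LEARNING_RATE = 0.005
BAG_FRACTION = 0.75
TREE_COMPLEXITY = 2
N_FOLDS = 10
MAX_TREES = 3000
TREE_STEP = 50


def extract_env(
    env_grid: EnvGridSeries | pd.DataFrame,
    site: tuple[float, float],
    date,
    radius_km: float,
) -> dict:
    """Mean environmental conditions within the detection radius of a site.

    Averages grid cells whose centers fall within ``radius_km`` (the
    equivalent-circle radius of the day's detection area); NPP is
    log-transformed after averaging. With no cell in radius the nearest
    cell is used and flagged.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    df = env_grid.data if isinstance(env_grid, EnvGridSeries) else env_grid
    date = pd.Timestamp(date)
    day = df[df["date"] == date]
    if day.empty:
        raise ValueError(f"no environmental data for {date.date()}")
    dist = haversine_km(site[0], site[1], day["lon"].to_numpy(), day["lat"].to_numpy())
    inside = dist <= radius_km
    flagged = False
    if not inside.any():
        inside = dist == dist.min()
        flagged = True
    sel = day[inside]
    return {
        "date": date,
        "sst": float(sel["sst"].mean()),
        "sst_anom": float(sel["sst_anom"].mean()),
        "log_npp": float(np.log(sel["npp"].mean())),
        "month": int(date.month),
        "n_cells": int(inside.sum()),
        "nearest_cell_fallback": flagged,
    }


def extract_env_series(
    env_grid: EnvGridSeries | pd.DataFrame,
    site: tuple[float, float],
    radius_km: float,
) -> pd.DataFrame:
    """Daily mean conditions within a fixed radius of a site.

    Vectorized form of :func:`extract_env` over every date in the grid;
    returns columns date, sst, sst_anom, log_npp, month, n_cells.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    df = env_grid.data if isinstance(env_grid, EnvGridSeries) else env_grid
    cells = df[["lon", "lat"]].drop_duplicates()
    dist = haversine_km(site[0], site[1], cells["lon"].to_numpy(), cells["lat"].to_numpy())
    inside = cells[dist <= radius_km]
    if inside.empty:
        inside = cells.iloc[[int(np.argmin(dist))]]
    sel = df.merge(inside, on=["lon", "lat"])
    out = (
        sel.groupby("date")
        .agg(sst=("sst", "mean"), sst_anom=("sst_anom", "mean"), npp=("npp", "mean"),
             n_cells=("sst", "size"))
        .reset_index()
    )
    out["log_npp"] = np.log(out["npp"])
    out["month"] = pd.DatetimeIndex(out["date"]).month
    return out.drop(columns="npp")


#: Within-peak season windows (months) for the seasonal model splits:
#: D-call spring peak Oct-Jan, D-call fall peak Apr-May, song fall peak
#: Apr-Jun. "all" fits the full year.
SEASON_WINDOWS = {
    ("dcalls", "spring"): (10, 11, 12, 1),
    ("dcalls", "fall"): (4, 5),
    ("sii", "fall"): (4, 5, 6),
}


def season_subset(data: pd.DataFrame, response: str, season: str) -> pd.DataFrame:
    """Rows inside the within-peak window for a response and season.

    ``response`` is ``dcalls`` or ``sii``; ``season`` is ``all``,
    ``spring`` (D calls only) or ``fall``.
    """
    if season == "all":
        return data
    months = SEASON_WINDOWS.get((response, season))
    if months is None:
        raise ValueError(f"no within-peak window for response={response!r} season={season!r}")
    month = pd.DatetimeIndex(data["date"]).month
    out = data[np.isin(month, months)]
    if out.empty:
        raise ValueError("season window contains no rows")
    return out


def _deviance(y: np.ndarray, mu: np.ndarray, kind: str) -> float:
    """Total deviance: unit Poisson deviance or squared error."""
    if kind == "poisson":
        mu = np.maximum(mu, 1e-10)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2 * np.sum(term - (y - mu)))
    return float(np.sum((y - mu) ** 2))


@dataclass
class BRTFit:
    """A fitted boosted-regression-tree model with its CV diagnostics."""

    model: LGBMRegressor
    predictors: list[str]
    response: str
    response_kind: str
    n_trees: int
    learning_rate: float
    bag_fraction: float
    tree_complexity: int
    cv_dev: float
    cv_cor: float
    train_dev_explained: float
    relative_influence: pd.Series = field(repr=False)
    training_means: pd.Series = field(repr=False)
    training_range: pd.DataFrame = field(repr=False)
    degenerate: bool = False


def fit_brt(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    response_kind: str = "poisson",
    learning_rate: float = LEARNING_RATE,
    bag_fraction: float = BAG_FRACTION,
    tree_complexity: int = TREE_COMPLEXITY,
    n_folds: int = N_FOLDS,
    max_trees: int = MAX_TREES,
    tree_step: int = TREE_STEP,
    seed: int = 0,
) -> BRTFit:
    """Fit a BRT with stagewise-CV tree-count selection.

    Each fold is boosted to ``max_trees``; held-out deviance is evaluated
    every ``tree_step`` trees and the count minimizing the mean CV deviance
    is kept. cv_dev is one minus the ratio of CV deviance to the null
    (intercept-only) deviance; cv_cor the Pearson correlation between the
    response and its CV predictions. The final model is refit on all rows
    at the selected size.
    """
    if len(data) < 50:
        raise ValueError("need at least 50 rows")
    missing = [p for p in predictors if p not in data.columns]
    if missing:
        raise ValueError(f"predictors missing from data: {missing}")
    y = data[response].to_numpy(dtype=float)
    if response_kind == "poisson":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("Poisson response must be non-negative integers")
    elif response_kind != "gaussian":
        raise ValueError("response_kind must be 'poisson' or 'gaussian'")
    X = data[predictors].astype(float)

    objective = "poisson" if response_kind == "poisson" else "regression"

    def make_model(n_estimators: int, rs: int) -> LGBMRegressor:
        return LGBMRegressor(
            objective=objective,
            n_estimators=n_estimators,
            learning_rate=learning_rate,
            subsample=bag_fraction,
            subsample_freq=1,
            max_depth=tree_complexity,
            num_leaves=tree_complexity + 1,
            min_child_samples=10,
            random_state=rs,
            n_jobs=1,
            verbose=-1,
        )

    checkpoints = np.arange(tree_step, max_trees + 1, tree_step)
    null_mu = np.full_like(y, y.mean())
    degenerate = float(np.var(y)) == 0.0

    if degenerate:
        model = make_model(tree_step, seed).fit(X, y)
        uniform = pd.Series(100.0 / len(predictors), index=predictors)
        return BRTFit(
            model=model, predictors=list(predictors), response=response,
            response_kind=response_kind, n_trees=tree_step,
            learning_rate=learning_rate, bag_fraction=bag_fraction,
            tree_complexity=tree_complexity, cv_dev=0.0, cv_cor=0.0,
            train_dev_explained=0.0, relative_influence=uniform,
            training_means=data[predictors].mean(),
            training_range=data[predictors].agg(["min", "max"]),
            degenerate=True,
        )

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_dev_at = np.zeros(checkpoints.size)
    cv_pred_at = {c: np.empty_like(y) for c in checkpoints}
    for f, (tr, te) in enumerate(kf.split(X)):
        m = make_model(int(max_trees), seed + f).fit(X.iloc[tr], y[tr])
        for ci, c in enumerate(checkpoints):
            mu = m.predict(X.iloc[te], num_iteration=int(c))
            cv_dev_at[ci] += _deviance(y[te], mu, response_kind)
            cv_pred_at[c][te] = mu
    best_i = int(np.argmin(cv_dev_at))
    best_trees = int(checkpoints[best_i])
    cv_pred = cv_pred_at[best_trees]

    null_dev = _deviance(y, null_mu, response_kind)
    cv_dev = 1.0 - cv_dev_at[best_i] / null_dev if null_dev > 0 else 0.0
    if np.std(cv_pred) > 0:
        cv_cor = float(stats.pearsonr(y, cv_pred)[0])
    else:
        cv_cor = 0.0

    model = make_model(best_trees, seed).fit(X, y)
    train_mu = model.predict(X)
    train_dev = _deviance(y, train_mu, response_kind)
    train_dev_explained = 1.0 - train_dev / null_dev if null_dev > 0 else 0.0

    gains = model.booster_.feature_importance(importance_type="gain").astype(float)
    total = gains.sum()
    influence = pd.Series(
        gains / total * 100.0 if total > 0 else np.full(len(predictors), np.nan),
        index=predictors,
    )
    return BRTFit(
        model=model,
        predictors=list(predictors),
        response=response,
        response_kind=response_kind,
        n_trees=best_trees,
        learning_rate=learning_rate,
        bag_fraction=bag_fraction,
        tree_complexity=tree_complexity,
        cv_dev=float(cv_dev),
        cv_cor=cv_cor,
        train_dev_explained=float(train_dev_explained),
        relative_influence=influence,
        training_means=data[predictors].mean(),
        training_range=data[predictors].agg(["min", "max"]),
        degenerate=total <= 0,
    )


def relative_influence(fit: BRTFit) -> pd.Series:
    """Per-predictor percent contribution (split-gain share), summing to 100."""
    return fit.relative_influence


def partial_dependence(
    fit: BRTFit,
    predictor: str,
    grid_size: int = 100,
    kind: str = "fixed_at_mean",
) -> pd.DataFrame:
    """Partial-dependence curve for one predictor.

    ``fixed_at_mean`` (default) traces predictions over a grid of the
    predictor with every other predictor held at its training mean;
    ``average`` is the standard marginalizing curve. Month uses the
    integer grid 1..12.
    """
    if predictor not in fit.predictors:
        raise ValueError(f"{predictor!r} not in model predictors")
    lo = fit.training_range.loc["min", predictor]
    hi = fit.training_range.loc["max", predictor]
    if predictor == "month":
        grid = np.arange(max(1, int(lo)), min(12, int(hi)) + 1, dtype=float)
    else:
        grid = np.linspace(lo, hi, grid_size)

    if kind == "fixed_at_mean":
        X = pd.DataFrame(
            {p: np.full(grid.size, fit.training_means[p]) for p in fit.predictors}
        )
        X[predictor] = grid
        yhat = fit.model.predict(X[fit.predictors])
    elif kind == "average":
        raise ValueError("marginalizing curves need data: use partial_dependence_average")
    else:
        raise ValueError("kind must be 'fixed_at_mean' or 'average'")
    return pd.DataFrame({predictor: grid, "fit": yhat})


def partial_dependence_average(
    fit: BRTFit, data: pd.DataFrame, predictor: str, grid_size: int = 50
) -> pd.DataFrame:
    """Standard marginalizing partial dependence (average prediction over
    the training rows with the predictor overridden)."""
    if predictor not in fit.predictors:
        raise ValueError(f"{predictor!r} not in model predictors")
    lo = fit.training_range.loc["min", predictor]
    hi = fit.training_range.loc["max", predictor]
    grid = np.linspace(lo, hi, grid_size)
    X = data[fit.predictors].copy()
    yhat = np.empty(grid.size)
    for i, g in enumerate(grid):
        X[predictor] = g
        yhat[i] = float(np.mean(fit.model.predict(X)))
    return pd.DataFrame({predictor: grid, "fit": yhat})
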
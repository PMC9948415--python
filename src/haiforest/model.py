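"""Random-forest prediction of the age-adjusted Healthy Aging Index.

Workflow: an 80/20 train/test split, grid-search tuning of the forest's
``mtry`` (features tried per split), ``ntree``, ``nodesize`` (minimum
terminal-node size) and ``maxnodes`` (maximum terminal nodes) under
five-fold cross-validation on the training set, evaluation on the held-out
test set against an exposure-free null model that predicts the training
mean, permutation importance expressed as the percentage increase in mean
squared error (%IncMSE), and partial dependence profiles.

Conventions
-----------
* R² is the squared Pearson correlation between predictions and observed
  outcomes; a constant-prediction model (the null model) has undefined
  correlation and is assigned R² = 0 by convention. The alternative
  1 - MSE/Var definition is available via ``r2_convention="residual"``.
* Permutation importance is computed on supplied (typically held-out)
  data: %IncMSE = 100 x mean over repeats of (MSE after permuting the
  feature - baseline MSE) / baseline MSE. Ranks break ties by feature name.
* All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold


@dataclass(frozen=True)
class RFParams:
    """One random-forest parameter combination (R-style naming)."""

    mtry: int
    ntree: int = 500
    nodesize: int = 5
    maxnodes: int | None = None

    def as_tuple(self) -> tuple:
        return (self.mtry, self.ntree, self.nodesize,
                np.inf if self.maxnodes is None else self.maxnodes)


@dataclass
class TuningGrid:
    mtry: Sequence[int]
    ntree: Sequence[int] = (500,)
    nodesize: Sequence[int] = (5, 25)
    maxnodes: Sequence[int | None] = (None, 64)
    cv_folds: int = 5
    train_fraction: float = 0.8
    seed: int = 0

    def combinations(self) -> list[RFParams]:
        combos = [
            RFParams(m, t, n, x)
            for m, t, n, x in itertools.product(self.mtry, self.ntree, self.nodesize, self.maxnodes)
        ]
        if not combos:
            raise ValueError("tuning grid is empty")
        return sorted(combos, key=RFParams.as_tuple)


def default_grid(n_features: int, seed: int = 0) -> TuningGrid:
    """Small default grid around the usual regression-forest heuristics."""
    mtry = sorted({max(1, n_features // 3), max(1, int(np.sqrt(n_features))), max(1, n_features // 2)})
    return TuningGrid(mtry=mtry, seed=seed)


@dataclass
class PredictionMetrics:
    rmse: float
    r2: float
    mae: float
    n_test: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "r2": self.r2, "mae": self.mae, "n_test": self.n_test}


@dataclass
class ImportanceRanking:
    """Features ordered by decreasing %IncMSE."""

    table: pd.DataFrame  # columns: feature, pct_inc_mse, rank
    n_repeats: int
    seed: int

    @property
    def features(self) -> list[str]:
        return list(self.table["feature"])

    def top(self, k: int) -> list[str]:
        return self.features[:k]


@dataclass
class PDPProfile:
    feature: str
    grid: np.ndarray
    average_prediction: np.ndarray


# ---------------------------------------------------------------------------
# splitting / fitting
# ---------------------------------------------------------------------------

def split_train_test(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Seeded random partition into ceil(f*n) training and the remaining test rows."""
    n = len(X)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    if len(y) != n:
        raise ValueError("outcome length does not match feature rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.ceil(train_fraction * n))
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return X.iloc[tr], X.iloc[te], y[tr], y[te]


def fit_rf(X: pd.DataFrame, y: np.ndarray, params: RFParams, seed: int = 0) -> RandomForestRegressor:
    model = RandomForestRegressor(
        n_estimators=params.ntree,
        max_features=min(params.mtry, X.shape[1]),
        min_samples_leaf=params.nodesize,
        max_leaf_nodes=params.maxnodes,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X.to_numpy(dtype=float), y)
    return model


def cv_rmse(
    X: pd.DataFrame,
    y: np.ndarray,
    params: RFParams,
    cv_folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean RMSE over k seeded CV folds for one parameter combination."""
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    rmses = []
    for tr, va in kf.split(X):
        if len(va) < 2 or len(tr) < 2:
            raise ValueError("cross-validation fold with fewer than 2 observations")
        model = fit_rf(X.iloc[tr], y[tr], params, seed=seed)
        pred = model.predict(X.iloc[va].to_numpy(dtype=float))
        rmses.append(float(np.sqrt(np.mean((y[va] - pred) ** 2))))
    return float(np.mean(rmses))


def tune_rf(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: TuningGrid,
) -> tuple[RFParams, pd.DataFrame]:
    """Evaluate every grid combination by mean CV RMSE; return the argmin.

    Ties (and the search order) are resolved lexicographically on the
    (mtry, ntree, nodesize, maxnodes) tuple, so the result is deterministic.
    """
    rows = []
    for params in grid.combinations():
        rows.append(
            {
                "mtry": params.mtry,
                "ntree": params.ntree,
                "nodesize": params.nodesize,
                "maxnodes": params.maxnodes,
                "cv_rmse": cv_rmse(X, y, params, cv_folds=grid.cv_folds, seed=grid.seed),
            }
        )
    table = pd.DataFrame(rows)
    best_idx = int(table["cv_rmse"].idxmin())  # first minimum in lexicographic order
    r = table.iloc[best_idx]
    best = RFParams(int(r["mtry"]), int(r["ntree"]), int(r["nodesize"]),
                    None if pd.isna(r["maxnodes"]) else int(r["maxnodes"]))
    return best, table


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _metrics(y_true: np.ndarray, y_pred: np.ndarray, r2_convention: str) -> PredictionMetrics:
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if r2_convention == "correlation":
        if np.std(y_pred) == 0.0 or np.std(y_true) == 0.0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    elif r2_convention == "residual":
        var = float(np.var(y_true))
        r2 = 0.0 if var == 0.0 else float(1.0 - np.mean(resid**2) / var)
    else:
        raise ValueError(f"unknown r2 convention {r2_convention!r}")
    return PredictionMetrics(rmse=rmse, r2=r2, mae=mae, n_test=len(y_true))


def evaluate(
    model: RandomForestRegressor,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    r2_convention: str = "correlation",
) -> PredictionMetrics:
    if len(X_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X_test.to_numpy(dtype=float))
    return _metrics(np.asarray(y_test, dtype=float), pred, r2_convention)


def null_metrics(
    y_train: np.ndarray,
    y_test: np.ndarray,
    r2_convention: str = "correlation",
) -> PredictionMetrics:
    """Exposure-free baseline predicting the training mean; R² = 0 by convention."""
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = np.full(len(y_test), float(np.mean(y_train)))
    return _metrics(np.asarray(y_test, dtype=float), pred, r2_convention)


# ---------------------------------------------------------------------------
# permutation importance (%IncMSE)
# ---------------------------------------------------------------------------

def permutation_importance(
    model: RandomForestRegressor,
    X: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceRanking:
    """%IncMSE ranking: percent rise in MSE when one feature is shuffled.

    For each feature the column is independently permuted ``n_repeats``
    times and the model re-scored; the importance is
    ``100 * mean(MSE_permuted - MSE_baseline) / MSE_baseline``. Features
    are ranked by decreasing importance, ties broken alphabetically.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if model.n_features_in_ != X.shape[1]:
        raise ValueError("data columns do not match the fitted model's features")
    rng = np.random.default_rng(seed)
    Xa = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    base_mse = float(np.mean((y - model.predict(Xa)) ** 2))
    rows = []
    for j, name in enumerate(X.columns):
        deltas = np.empty(n_repeats)
        for r in range(n_repeats):
            Xp = Xa.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            mse = float(np.mean((y - model.predict(Xp)) ** 2))
            deltas[r] = mse - base_mse
        rows.append({"feature": name, "pct_inc_mse": 100.0 * float(np.mean(deltas)) / base_mse})
    table = pd.DataFrame(rows).sort_values(
        ["pct_inc_mse", "feature"], ascending=[False, True], kind="mergesort"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceRanking(table=table.reset_index(drop=True), n_repeats=n_repeats, seed=seed)


# ---------------------------------------------------------------------------
# partial dependence
# ---------------------------------------------------------------------------

def partial_dependence(
    model: RandomForestRegressor,
    X_background: pd.DataFrame,
    feature: str,
    grid: np.ndarray | None = None,
    n_grid: int = 25,
) -> PDPProfile:
    """Average model prediction as one feature sweeps a grid.

    All other features keep their original background values; for each grid
    value v the feature column is overwritten by v and the predictions are
    averaged. The default grid is ``n_grid`` equally spaced points between
    the feature's 5th and 95th percentiles (collapsing to the unique values
    when the feature is near-constant).
    """
    if feature not in X_background.columns:
        raise KeyError(f"feature {feature!r} not in background data")
    col = X_background[feature].to_numpy(dtype=float)
    if grid is None:
        lo, hi = np.quantile(col, [0.05, 0.95])
        if hi <= lo:
            grid = np.unique(col)
        else:
            grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty partial-dependence grid")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be increasing")
    Xa = X_background.to_numpy(dtype=float).copy()
    j = list(X_background.columns).index(feature)
    avg = np.empty(grid.size)
    for k, v in enumerate(grid):
        Xa[:, j] = v
        avg[k] = float(np.mean(model.predict(Xa)))
    return PDPProfile(feature=feature, grid=grid, average_prediction=avg)
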
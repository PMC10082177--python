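"""Boosted-regression-tree surrogate of the sensitivity sweep.

Relates the four varied scenario parameters to the relative sneaker
success score with gradient-boosted regression trees, following the
standard ecological BRT workflow: a 70/30 train/test split; a 36-cell
hyperparameter grid (bag fraction 0.5/0.6/0.7 × tree complexity 2/3/4 ×
learning rate 0.01/0.005/0.001/0.0005) under squared-error (Gaussian)
loss, scored by cross-validated mean absolute error with the tree count
chosen along the boosting path; backward elimination of non-informative
predictors; bootstrap-averaged relative importances and partial-dependence
curves with min/max envelopes; and held-out validation by Spearman rank
correlation and MAE.

Usage follows the model/results idiom::

    model = SneakerSuccessBRT(results_table)        # or .from_results_csv
    res = model.fit()
    print(res.summary())
    res.relative_importance        # % per retained predictor, sums to 100
    res.partial_dependence["assortative_c"]         # value/mean/lo/hi grid

Tree complexity (the number of splits per tree, as in the gbm/dismo
convention) maps to best-first trees with ``max_leaf_nodes = complexity+1``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import clone
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.metrics import mean_absolute_error
from sklearn.model_selection import KFold

from .sensitivity import PARAM_NAMES

__all__ = [
    "SurrogateConfig",
    "SurrogateResults",
    "SneakerSuccessBRT",
    "split_train_test",
    "tune_and_fit",
    "backward_eliminate",
    "importance_and_partial_dependence",
    "validate",
]


@dataclass
class SurrogateConfig:
    train_fraction: float = 0.7
    bag_fractions: tuple = (0.5, 0.6, 0.7)
    tree_complexities: tuple = (2, 3, 4)
    learning_rates: tuple = (0.01, 0.005, 0.001, 0.0005)
    loss: str = "squared_error"      # Gaussian error distribution
    n_bootstrap: int = 1000
    cv_folds: int = 4
    max_trees: int = 800             # boosting-path length searched per cell
    pd_grid_points: int = 25
    elimination_tolerance_se: float = 1.0  # allowed MAE increase, in CV SEs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly in (0, 1)")

    @property
    def grid(self) -> list[tuple[float, int, float]]:
        return list(itertools.product(
            self.bag_fractions, self.tree_complexities, self.learning_rates
        ))


def split_train_test(results_table: pd.DataFrame, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive random train/test split of the results table."""
    n = len(results_table)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train = results_table.iloc[np.sort(perm[:n_train])]
    test = results_table.iloc[np.sort(perm[n_train:])]
    return train, test


def _make_gbr(bag: float, complexity: int, lr: float, n_trees: int,
              seed: int) -> GradientBoostingRegressor:
    return GradientBoostingRegressor(
        loss="squared_error",
        subsample=bag,
        max_leaf_nodes=complexity + 1,
        max_depth=None,
        learning_rate=lr,
        n_estimators=n_trees,
        random_state=seed,
    )


def _cv_mae_path(X: np.ndarray, y: np.ndarray, bag: float, complexity: int,
                 lr: float, config: SurrogateConfig):
    """Cross-validated MAE along the boosting path.

    Returns (best_mae, best_n_trees, se_at_best): the minimum of the
    fold-averaged MAE curve over tree counts 1..max_trees, the tree count
    achieving it, and the standard error across folds there.
    """
    folds = min(config.cv_folds, len(y) // 2)
    kf = KFold(n_splits=folds, shuffle=True, random_state=config.seed)
    curves = []
    for tr, va in kf.split(X):
        gbr = _make_gbr(bag, complexity, lr, config.max_trees, config.seed)
        gbr.fit(X[tr], y[tr])
        curves.append(np.array([
            mean_absolute_error(y[va], pred) for pred in gbr.staged_predict(X[va])
        ]))
    curves = np.vstack(curves)
    mean_curve = curves.mean(axis=0)
    best = int(mean_curve.argmin())
    se = float(curves[:, best].std(ddof=1) / np.sqrt(curves.shape[0]))
    return float(mean_curve[best]), best + 1, se


def tune_and_fit(train: pd.DataFrame, config: SurrogateConfig,
                 predictors: list[str] | None = None, response: str = "score"):
    """Grid-tune the BRT on the training rows and fit the selected model.

    Fits every cell of the 36-point hyperparameter grid, scores each by
    cross-validated MAE (tree count chosen along the boosting path), and
    refits the lowest-MAE cell on the full training set.

    Returns ``(model, hyperparameters, grid_table)``.  A zero-variance
    response is flagged: a constant (mean) predictor is returned with
    ``hyperparameters["degenerate"] = True``.
    """
    predictors = list(predictors or PARAM_NAMES)
    X = train[predictors].to_numpy(dtype=float)
    y = train[response].to_numpy(dtype=float)
    if len(y) == 0:
        raise ValueError("empty training set")
    if np.allclose(y, y[0]):
        model = DummyRegressor(strategy="mean").fit(X, y)
        return model, {"degenerate": True, "predictors": predictors}, pd.DataFrame()

    rows = []
    for bag, complexity, lr in config.grid:
        mae, n_trees, se = _cv_mae_path(X, y, bag, complexity, lr, config)
        rows.append({
            "bag_fraction": bag, "tree_complexity": complexity,
            "learning_rate": lr, "cv_mae": mae, "n_trees": n_trees, "cv_se": se,
        })
    grid_table = pd.DataFrame(rows).sort_values("cv_mae").reset_index(drop=True)
    best = grid_table.iloc[0]
    hyper = {
        "bag_fraction": float(best.bag_fraction),
        "tree_complexity": int(best.tree_complexity),
        "learning_rate": float(best.learning_rate),
        "n_trees": int(best.n_trees),
        "cv_mae": float(best.cv_mae),
        "cv_se": float(best.cv_se),
        "degenerate": False,
        "predictors": predictors,
    }
    model = _make_gbr(hyper["bag_fraction"], hyper["tree_complexity"],
                      hyper["learning_rate"], hyper["n_trees"], config.seed)
    model.fit(X, y)
    return model, hyper, grid_table


def backward_eliminate(model, train: pd.DataFrame, config: SurrogateConfig,
                       predictors: list[str] | None = None,
                       response: str = "score"):
    """Iteratively drop the least-important predictor while CV MAE holds.

    A drop is kept when the cross-validated MAE does not worsen by more
    than ``elimination_tolerance_se`` CV standard errors.  Returns
    ``(retained_predictors, refit_model)``; at least one predictor is
    always retained, and a constant-response model retains everything.
    """
    predictors = list(predictors or PARAM_NAMES)
    if isinstance(model, DummyRegressor):
        return predictors, model
    params = model.get_params()
    bag = params["subsample"]
    complexity = params["max_leaf_nodes"] - 1
    lr = params["learning_rate"]
    y = train[response].to_numpy(dtype=float)

    def cv(cols):
        return _cv_mae_path(train[cols].to_numpy(dtype=float), y, bag, complexity,
                            lr, config)

    def refit(cols, n_trees):
        m = _make_gbr(bag, complexity, lr, n_trees, config.seed)
        m.fit(train[cols].to_numpy(dtype=float), y)
        return m

    current = list(predictors)
    base_mae, base_n, base_se = cv(current)
    fitted = refit(current, base_n)
    while len(current) > 1:
        order = np.argsort(fitted.feature_importances_)
        candidate = [c for i, c in enumerate(current) if i != order[0]]
        mae, n_trees, se = cv(candidate)
        if mae <= base_mae + config.elimination_tolerance_se * base_se:
            current, base_mae, base_se = candidate, mae, se
            fitted = refit(current, n_trees)
        else:
            break
    return current, fitted


def _pd_curve(model, X: np.ndarray, col: int, grid: np.ndarray) -> np.ndarray:
    """Partial dependence: mean prediction over the empirical distribution
    of the other predictors, at each grid value of predictor ``col``."""
    out = np.empty(grid.size)
    work = X.copy()
    for i, v in enumerate(grid):
        work[:, col] = v
        out[i] = model.predict(work).mean()
    return out


def importance_and_partial_dependence(model, data: pd.DataFrame,
                                      config: SurrogateConfig,
                                      predictors: list[str] | None = None,
                                      response: str = "score"):
    """Bootstrap-averaged relative importances and partial dependence.

    The training rows are resampled with replacement ``n_bootstrap`` times
    and the model refitted on each resample; importances are averaged and
    normalized to sum to 100%, and each predictor's partial-dependence
    curve carries the bootstrap mean and min/max envelope.

    Returns ``(relative_importance: Series, partial_dependence: dict of
    DataFrame(value, mean, lo, hi))``.
    """
    predictors = list(predictors or PARAM_NAMES)
    X = data[predictors].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    grids = {p: np.linspace(X[:, j].min(), X[:, j].max(), config.pd_grid_points)
             for j, p in enumerate(predictors)}

    if isinstance(model, DummyRegressor):
        imp = pd.Series(100.0 / len(predictors), index=predictors)
        flat = {p: pd.DataFrame({"value": g, "mean": model.predict(X).mean(),
                                 "lo": np.nan, "hi": np.nan})
                for p, g in grids.items()}
        return imp, flat

    rng = np.random.default_rng(config.seed)
    n = len(y)
    importances = np.zeros((config.n_bootstrap, len(predictors)))
    curves = {p: np.zeros((config.n_bootstrap, config.pd_grid_points))
              for p in predictors}
    for b in range(config.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        m = clone(model)
        m.set_params(random_state=int(rng.integers(2**31)))
        m.fit(X[idx], y[idx])
        importances[b] = m.feature_importances_
        for j, p in enumerate(predictors):
            curves[p][b] = _pd_curve(m, X, j, grids[p])

    mean_imp = importances.mean(axis=0)
    total = mean_imp.sum()
    rel = mean_imp / total * 100.0 if total > 0 else np.full(len(predictors),
                                                            100.0 / len(predictors))
    relative_importance = pd.Series(rel, index=predictors).sort_values(ascending=False)
    partial_dependence = {
        p: pd.DataFrame({
            "value": grids[p],
            "mean": curves[p].mean(axis=0),
            "lo": curves[p].min(axis=0),
            "hi": curves[p].max(axis=0),
        })
        for p in predictors
    }
    return relative_importance, partial_dependence


def validate(model, test: pd.DataFrame, predictors: list[str] | None = None,
             response: str = "score") -> dict:
    """Held-out validation: Spearman rank correlation (and its square,
    a rank-based R²) plus mean absolute error."""
    predictors = list(predictors or PARAM_NAMES)
    if len(test) < 3:
        raise ValueError("test set too small for a rank correlation (need >= 3)")
    X = test[predictors].to_numpy(dtype=float)
    y = test[response].to_numpy(dtype=float)
    pred = model.predict(X)
    if np.allclose(pred, pred[0]) or np.allclose(y, y[0]):
        rho = 0.0
    else:
        rho = float(spearmanr(y, pred).statistic)
    return {
        "spearman": rho,
        "spearman_sq": rho**2,
        "mae": float(mean_absolute_error(y, pred)),
    }


# -- model / results objects -------------------------------------------------

class SneakerSuccessBRT:
    """BRT surrogate model of relative sneaker success vs scenario parameters.

    Parameters
    ----------
    data : DataFrame
        Sensitivity results table; must contain the predictor columns and
        the response column.
    response : str
        Response column name (default ``"score"``).
    predictors : list of str, optional
        Predictor columns (default: the four varied scenario parameters).
    config : SurrogateConfig, optional
    """

    def __init__(self, data: pd.DataFrame, response: str = "score",
                 predictors: list[str] | None = None,
                 config: SurrogateConfig | None = None):
        self.data = data.reset_index(drop=True)
        self.response = response
        self.predictors = list(predictors or PARAM_NAMES)
        self.config = config or SurrogateConfig()
        missing = [c for c in self.predictors + [response] if c not in data.columns]
        if missing:
            raise ValueError(f"results table missing columns: {missing}")

    @classmethod
    def from_results_csv(cls, path, **kwargs) -> "SneakerSuccessBRT":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, seed: int | None = None) -> "SurrogateResults":
        """Run the full workflow: split, tune, eliminate, bootstrap, validate."""
        config = self.config
        if seed is not None:
            config = SurrogateConfig(**{**config.__dict__, "seed": seed})
        train, test = split_train_test(self.data, config.train_fraction, config.seed)
        model, hyper, grid = tune_and_fit(train, config, self.predictors, self.response)
        if hyper.get("degenerate"):
            retained, final = self.predictors, model
        else:
            retained, final = backward_eliminate(model, train, config,
                                                 self.predictors, self.response)
        importance, pdp = importance_and_partial_dependence(
            final, train, config, retained, self.response
        )
        val = validate(final, test, retained, self.response)
        return SurrogateResults(
            model=final,
            selected_hyperparameters=hyper,
            grid=grid,
            retained_predictors=retained,
            relative_importance=importance,
            partial_dependence=pdp,
            validation=val,
            n_train=len(train),
            n_test=len(test),
            config=config,
        )


@dataclass
class SurrogateResults:
    """Fitted surrogate: estimates, envelopes, diagnostics."""

    model: object
    selected_hyperparameters: dict
    grid: pd.DataFrame
    retained_predictors: list[str]
    relative_importance: pd.Series
    partial_dependence: dict
    validation: dict
    n_train: int
    n_test: int
    config: SurrogateConfig = field(repr=False, default=None)

    def pd_slope(self, predictor: str) -> float:
        """Least-squares slope of the mean partial-dependence curve: a
        one-number summary of the direction of the fitted effect."""
        curve = self.partial_dependence[predictor]
        return float(np.polyfit(curve["value"], curve["mean"], 1)[0])

    def summary(self) -> str:
        h = self.selected_hyperparameters
        lines = [
            "Sneaker-success BRT surrogate",
            "=" * 46,
            f"training rows: {self.n_train}   test rows: {self.n_test}",
        ]
        if h.get("degenerate"):
            lines.append("response is constant: mean predictor returned")
        else:
            lines += [
                (f"selected: bag={h['bag_fraction']}, complexity={h['tree_complexity']}, "
                 f"lr={h['learning_rate']}, trees={h['n_trees']}"),
                f"cross-validated MAE: {h['cv_mae']:.4f} (SE {h['cv_se']:.4f})",
            ]
        lines.append(f"retained predictors: {', '.join(self.retained_predictors)}")
        lines.append("-" * 46)
        lines.append(f"{'predictor':<32}{'importance %':>12}")
        for name, v in self.relative_importance.items():
            lines.append(f"{name:<32}{v:>12.1f}")
        lines.append("-" * 46)
        lines.append(
            f"validation: Spearman rho={self.validation['spearman']:.3f} "
            f"(rho^2={self.validation['spearman_sq']:.3f}), "
            f"MAE={self.validation['mae']:.4f}"
        )
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "selected_hyperparameters": {
                k: v for k, v in self.selected_hyperparameters.items()
                if k != "predictors"
            },
            "retained_predictors": self.retained_predictors,
            "relative_importance": self.relative_importance.to_dict(),
            "validation": self.validation,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def write_partial_dependence(self, out_dir) -> None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        for name, curve in self.partial_dependence.items():
            curve.to_csv(os.path.join(out_dir, f"pd_{name}.csv"), index=False)
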
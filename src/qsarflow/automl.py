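"""Four-stage automated modeling workflow with super-learner stacking.

Stages, run in order by :func:`run_automl`:

1. **Feature selection** — a screening learner (gradient boosting by default)
   is fit ``n_try`` times with different seeds; per-feature importances are
   averaged and normalized so the top feature scores 1.000, and features at
   or above a relative-importance threshold are kept.
2. **Algorithm selection** — six base-learner families: random forest,
   extremely randomized trees, gradient boosting, extreme gradient boosting
   (xgboost), regularized linear models, and a small fully connected neural
   network.
3. **Model development / parameter optimization** — per family, a random
   search draws hyperparameter settings (log-uniform for scale-like
   parameters); every candidate is fit fold-by-fold to produce out-of-fold
   predictions and a cross-validated RMSE/R².
4. **Stacking** — a super learner combines the candidates: the metalearner
   is a linear model with non-negative weights and Lasso or elastic-net
   regularization, trained on the out-of-fold prediction matrix, with its
   penalty strength chosen by inner cross-validation.  Two ensembles are
   built — one over all candidates, one over the best candidate per family —
   and the lower-RMSE one is returned.

An ordinary-least-squares baseline over the same selected features and folds
(:func:`fit_linear_baseline`) quantifies how much of the signal is nonlinear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor
from xgboost import XGBRegressor

from .metrics import CVMetrics, kfold_split, r_squared, rmse

FAMILIES = (
    "random_forest",
    "extremely_randomized_trees",
    "gradient_boosting",
    "extreme_gradient_boosting",
    "linear_glm",
    "neural_net",
)


# -- specs and candidates -----------------------------------------------------

@dataclass(frozen=True)
class BaseLearnerSpec:
    family: str
    params: tuple[tuple[str, object], ...]
    seed: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")

    @property
    def params_dict(self) -> dict:
        return dict(self.params)


@dataclass
class Candidate:
    """A fitted base learner: spec, out-of-fold predictions, CV metrics."""

    candidate_id: str
    spec: BaseLearnerSpec
    oof: np.ndarray
    metrics: CVMetrics
    model: object  # refit on the full training set, used for new predictions

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.model.predict(np.asarray(X, dtype=float)), dtype=float)


def _loguniform(rng, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _sample_params(family: str, rng: np.random.Generator) -> dict:
    if family in ("random_forest", "extremely_randomized_trees"):
        return {
            "n_estimators": int(rng.integers(50, 201)),
            "max_depth": int(rng.integers(4, 17)),
            "max_features": float(rng.uniform(0.3, 1.0)),
            "min_samples_leaf": int(rng.integers(1, 6)),
        }
    if family == "gradient_boosting":
        return {
            "n_estimators": int(rng.integers(50, 201)),
            "learning_rate": _loguniform(rng, 0.01, 0.3),
            "max_depth": int(rng.integers(2, 6)),
            "subsample": float(rng.uniform(0.6, 1.0)),
        }
    if family == "extreme_gradient_boosting":
        return {
            "n_estimators": int(rng.integers(50, 301)),
            "learning_rate": _loguniform(rng, 0.01, 0.3),
            "max_depth": int(rng.integers(2, 7)),
            "subsample": float(rng.uniform(0.6, 1.0)),
            "colsample_bytree": float(rng.uniform(0.5, 1.0)),
            "reg_lambda": _loguniform(rng, 0.1, 10.0),
        }
    if family == "linear_glm":
        return {
            "alpha": _loguniform(rng, 1e-4, 10.0),
            "l1_ratio": float(rng.uniform(0.0, 1.0)),
        }
    if family == "neural_net":
        n_layers = int(rng.integers(1, 4))
        widths = tuple(int(rng.choice([16, 32, 64])) for _ in range(n_layers))
        return {
            "hidden_layer_sizes": widths,
            "alpha": _loguniform(rng, 1e-6, 1e-2),
            "learning_rate_init": _loguniform(rng, 1e-4, 1e-2),
        }
    raise ValueError(f"unknown family {family!r}")


def _make_estimator(spec: BaseLearnerSpec):
    params = spec.params_dict
    if spec.family == "random_forest":
        return RandomForestRegressor(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "extremely_randomized_trees":
        return ExtraTreesRegressor(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "gradient_boosting":
        return GradientBoostingRegressor(random_state=spec.seed, **params)
    if spec.family == "extreme_gradient_boosting":
        return XGBRegressor(
            random_state=spec.seed, n_jobs=1, verbosity=0, tree_method="hist", **params
        )
    if spec.family == "linear_glm":
        return ElasticNet(random_state=spec.seed, max_iter=5000, **params)
    if spec.family == "neural_net":
        return MLPRegressor(
            random_state=spec.seed, max_iter=200, early_stopping=False, **params
        )
    raise ValueError(f"unknown family {spec.family!r}")


def _fit_candidate(
    spec: BaseLearnerSpec,
    candidate_id: str,
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
) -> Candidate:
    oof = np.empty_like(y, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence / ElasticNet coord-descent chatter
        for f in np.unique(folds):
            test = folds == f
            est = clone(_make_estimator(spec))
            est.fit(X[~test], y[~test])
            oof[test] = est.predict(X[test])
        final = clone(_make_estimator(spec))
        final.fit(X, y)
    return Candidate(
        candidate_id=candidate_id,
        spec=spec,
        oof=oof,
        metrics=CVMetrics.from_oof(y, oof, folds),
        model=final,
    )


def random_search(
    family: str,
    X,
    y,
    folds: np.ndarray,
    budget: int = 10,
    seed: int = 0,
) -> list[Candidate]:
    """``budget`` random hyperparameter draws for one family, each fit per fold."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(budget):
        params = _sample_params(family, rng)
        spec = BaseLearnerSpec(
            family=family,
            params=tuple(sorted(params.items())),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(_fit_candidate(spec, f"{family}_{i}", X, y, folds))
    return out


# -- feature selection --------------------------------------------------------

@dataclass
class FeatureSubset:
    """Columns surviving the importance screen, with normalized scores."""

    names: list[str]
    relative_importance: dict[str, float]
    threshold: float

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("feature subset cannot be empty")


def select_features(
    X: pd.DataFrame,
    y,
    *,
    n_try: int = 5,
    threshold: float = 0.05,
    screen_family: str = "gradient_boosting",
    seed: int = 0,
) -> FeatureSubset:
    """Importance screening: average over ``n_try`` seeded fits, normalize by
    the maximum (top feature = 1.000), keep features ≥ ``threshold``.

    The top-ranked feature is always kept even if the threshold exceeds every
    other score.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if n_try < 1:
        raise ValueError("n_try must be >= 1")
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    importances = np.zeros(X.shape[1])
    # stochastic boosting with many shallow trees: subsampling lets later
    # trees pick up weak components once strong ones are exhausted
    screen_params = (
        (("n_estimators", 300), ("max_depth", 3), ("subsample", 0.7))
        if screen_family == "gradient_boosting" else ()
    )
    for i in range(n_try):
        spec = BaseLearnerSpec(screen_family, params=screen_params, seed=seed + i)
        est = _make_estimator(spec)
        est.fit(Xv, y)
        if hasattr(est, "feature_importances_"):
            importances += np.asarray(est.feature_importances_, dtype=float)
        else:
            importances += np.abs(np.asarray(est.coef_, dtype=float))
    importances /= n_try
    top = importances.max()
    if top <= 0:
        raise ValueError("screening model assigned zero importance everywhere")
    relative = importances / top
    scores = dict(zip(X.columns, relative.tolist()))
    names = [c for c, s in scores.items() if s >= threshold]
    if not names:
        names = [max(scores, key=scores.get)]
    return FeatureSubset(
        names=names,
        relative_importance={c: scores[c] for c in names},
        threshold=threshold,
    )


# -- stacking -----------------------------------------------------------------

def _nonneg_meta(penalty: str, lam: float, seed: int):
    if lam == 0.0:
        return LinearRegression(positive=True)
    if penalty == "lasso":
        return Lasso(alpha=lam, positive=True, max_iter=50000, random_state=seed)
    if penalty == "elastic":
        return ElasticNet(
            alpha=lam, l1_ratio=0.5, positive=True, max_iter=50000, random_state=seed
        )
    raise ValueError(f"unknown penalty {penalty!r}")


@dataclass
class StackedModel:
    """Super learner: non-negative linear combination of base candidates."""

    base: list[Candidate]
    weights: np.ndarray
    intercept: float
    mode: str
    penalty: str
    lambda_: float
    cv_metrics: CVMetrics

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("metalearner weights must be non-negative")

    def predict(self, X) -> np.ndarray:
        Z = np.column_stack([c.predict(X) for c in self.base])
        return self.intercept + Z @ self.weights

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "penalty": self.penalty,
            "lambda": self.lambda_,
            "intercept": self.intercept,
            "weights": {
                c.candidate_id: float(w) for c, w in zip(self.base, self.weights)
            },
            "cv_rmse": self.cv_metrics.rmse,
            "cv_r2": self.cv_metrics.r2,
        }


def best_of_family(candidates: Sequence[Candidate]) -> list[Candidate]:
    """Lowest-CV-RMSE candidate per family (ties broken by id)."""
    best: dict[str, Candidate] = {}
    for c in sorted(candidates, key=lambda c: (c.metrics.rmse, c.candidate_id)):
        best.setdefault(c.spec.family, c)
    return [best[f] for f in sorted(best)]


def fit_super_learner(
    candidates: Sequence[Candidate],
    y,
    *,
    mode: str = "all",
    penalty: str = "lasso",
    lambdas: Sequence[float] | None = None,
    folds: np.ndarray | None = None,
    seed: int = 0,
) -> StackedModel:
    """Fit the non-negative linear metalearner on out-of-fold predictions.

    Penalty strength is chosen from ``lambdas`` (default: 0 plus 20
    log-spaced values in [1e-5, 1]) by inner 5-fold cross-validation on the
    meta-feature matrix; pass ``lambdas=[0]`` for the unpenalized
    non-negative least-squares limit.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one base candidate")
    n = candidates[0].oof.size
    for c in candidates:
        if c.oof.size != n:
            raise ValueError("candidates disagree on fold assignment length")
    y = np.asarray(y, dtype=float)
    if mode == "best_of_family":
        candidates = best_of_family(candidates)
    elif mode != "all":
        raise ValueError(f"unknown ensemble mode {mode!r}")

    Z = np.column_stack([c.oof for c in candidates])
    if lambdas is None:
        lambdas = [0.0] + np.logspace(-5, 0, 20).tolist()
    lambdas = sorted(set(float(l) for l in lambdas))

    if len(lambdas) > 1:
        inner = kfold_split(n, k=min(5, n), seed=seed + 1)
        best_lam, best_err = lambdas[0], np.inf
        for lam in lambdas:
            preds = np.empty(n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for f in np.unique(inner):
                    test = inner == f
                    m = _nonneg_meta(penalty, lam, seed)
                    m.fit(Z[~test], y[~test])
                    preds[test] = m.predict(Z[test])
            err = rmse(y, preds)
            if err < best_err - 1e-12:
                best_lam, best_err = lam, err
    else:
        best_lam = lambdas[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        meta = _nonneg_meta(penalty, best_lam, seed)
        meta.fit(Z, y)
    weights = np.maximum(np.asarray(meta.coef_, dtype=float), 0.0)
    intercept = float(meta.intercept_)
    stacked_oof = intercept + Z @ weights
    folds = folds if folds is not None else kfold_split(n, k=min(10, n), seed=seed)
    return StackedModel(
        base=candidates,
        weights=weights,
        intercept=intercept,
        mode=mode,
        penalty=penalty,
        lambda_=best_lam,
        cv_metrics=CVMetrics.from_oof(y, stacked_oof, folds),
    )


# -- baseline and orchestration ----------------------------------------------

def fit_linear_baseline(
    X, y, k: int = 10, seed: int = 0, folds: np.ndarray | None = None
) -> CVMetrics:
    """Ordinary least squares on the selected features, same CV folds.

    Falls back to a minimally ridge-regularized fit (with a warning) when a
    training split is rank-deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = kfold_split(len(y), k=k, seed=seed) if folds is None else folds
    oof = np.empty_like(y)
    for f in np.unique(folds):
        test = folds == f
        Xtr = X[~test]
        if np.linalg.matrix_rank(Xtr) < Xtr.shape[1]:
            warnings.warn("rank-deficient design; using ridge fallback", stacklevel=2)
            est = Ridge(alpha=1e-6)
        else:
            est = LinearRegression()
        est.fit(Xtr, y[~test])
        oof[test] = est.predict(X[test])
    return CVMetrics.from_oof(y, oof, folds)


@dataclass(frozen=True)
class AutoMLConfig:
    model_budget: int = 10          # random-search draws per family
    n_try: int = 5                  # feature-screening repetitions
    fs_threshold: float = 0.05      # relative-importance cutoff
    k: int = 10                     # CV folds
    seed: int = 0
    families: tuple[str, ...] = FAMILIES
    penalty: str = "lasso"
    lambdas: tuple[float, ...] | None = None
    impute: str = "fold_safe"       # or "global"


@dataclass
class AutoMLResult:
    model: StackedModel
    features: FeatureSubset
    leaderboard: pd.DataFrame
    candidates: list[Candidate]
    ensembles: dict[str, StackedModel]
    folds: np.ndarray


def _impute_global(X: pd.DataFrame) -> pd.DataFrame:
    return X.fillna(X.mean()) if X.isna().any().any() else X


def run_automl(X: pd.DataFrame, y, config: AutoMLConfig = AutoMLConfig()) -> AutoMLResult:
    """Execute the four-stage workflow and return the better of the two
    stacked ensembles, the selected features, and a full leaderboard."""
    if len(X) != len(np.asarray(y)):
        raise ValueError("X and y are not aligned")
    if config.model_budget < 1:
        raise ValueError("budget must allow at least one model per family")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(config.seed)

    X_screen = _impute_global(X)  # screening uses globally imputed values
    subset = select_features(
        X_screen, y,
        n_try=config.n_try, threshold=config.fs_threshold, seed=config.seed,
    )
    folds = kfold_split(len(y), k=config.k, seed=config.seed)

    if config.impute == "fold_safe" and X[subset.names].isna().any().any():
        X_sel = X[subset.names].copy()
        for f in np.unique(folds):
            train_means = X_sel[folds != f].mean()
            X_sel.loc[folds == f] = X_sel.loc[folds == f].fillna(train_means)
        X_sel = X_sel.fillna(X_sel.mean())  # columns empty in some train split
    else:
        X_sel = _impute_global(X[subset.names])
    Xv = X_sel.to_numpy(dtype=float)

    candidates: list[Candidate] = []
    for family in config.families:
        candidates.extend(
            random_search(
                family, Xv, y, folds,
                budget=config.model_budget,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )

    ensembles = {
        m: fit_super_learner(
            candidates, y, mode=m, penalty=config.penalty,
            lambdas=config.lambdas, folds=folds, seed=config.seed,
        )
        for m in ("all", "best_of_family")
    }

    rows = [
        {
            "id": c.candidate_id, "kind": "base", "family": c.spec.family,
            "n_models": 1, "cv_rmse": c.metrics.rmse, "cv_r2": c.metrics.r2,
        }
        for c in candidates
    ]
    for name, ens in ensembles.items():
        rows.append({
            "id": f"stacked_{name}", "kind": "ensemble", "family": "stacked",
            "n_models": len(ens.base),
            "cv_rmse": ens.cv_metrics.rmse, "cv_r2": ens.cv_metrics.r2,
        })
    leaderboard = (
        pd.DataFrame(rows)
        .sort_values(["cv_rmse", "n_models", "id"], kind="mergesort")
        .reset_index(drop=True)
    )

    best = min(
        ensembles.values(),
        key=lambda e: (e.cv_metrics.rmse, len(e.base), e.mode),
    )
    return AutoMLResult(
        model=best,
        features=subset,
        leaderboard=leaderboard,
        candidates=candidates,
        ensembles=ensembles,
        folds=folds,
    )
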
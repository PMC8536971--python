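"""Cross-validation plumbing and goodness-of-fit metrics.

RMSE = sqrt(mean((pred − obs)²)) and R² = 1 − SS_res/SS_tot, with SS_tot
taken about the observed mean; both are evaluated on pooled out-of-fold
predictions from seeded 10-fold cross-validation unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold


def rmse(obs, pred) -> float:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def r_squared(obs, pred) -> float:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined for constant observations")
    ss_res = float(np.sum((pred - obs) ** 2))
    return 1.0 - ss_res / ss_tot


def kfold_split(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Seeded fold assignment: array of fold ids in [0, k), sizes differ ≤ 1."""
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    assignment = np.empty(n, dtype=int)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n))):
        assignment[test_idx] = fold
    return assignment


@dataclass
class CVMetrics:
    """Pooled and per-fold cross-validated performance."""

    rmse: float
    r2: float
    n: int
    per_fold_rmse: list[float] = field(default_factory=list)
    per_fold_r2: list[float] = field(default_factory=list)

    @classmethod
    def from_oof(cls, obs, oof_pred, folds: np.ndarray) -> "CVMetrics":
        obs = np.asarray(obs, dtype=float)
        oof_pred = np.asarray(oof_pred, dtype=float)
        per_rmse, per_r2 = [], []
        for f in np.unique(folds):
            mask = folds == f
            per_rmse.append(rmse(obs[mask], oof_pred[mask]))
            # a tiny fold can be pKi-constant by chance; pooled R² still defined
            try:
                per_r2.append(r_squared(obs[mask], oof_pred[mask]))
            except ValueError:
                per_r2.append(float("nan"))
        return cls(
            rmse=rmse(obs, oof_pred),
            r2=r_squared(obs, oof_pred),
            n=int(obs.size),
            per_fold_rmse=per_rmse,
            per_fold_r2=per_r2,
        )
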
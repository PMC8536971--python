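"""Shapley-value attribution for fitted regression models.

Each prediction is decomposed into a base value (the expected model output
over a background sample) plus one additive contribution per feature.  The
contribution of feature j is its Shapley value: the average over orderings of
the change in the model's expected output when j is revealed, with unrevealed
features marginalized by substituting background-sample values (the
interventional/marginal expectation).

Two estimators are provided:

* ``exact`` — full coalition enumeration, feasible up to 12 features
  (2^12 coalitions × background evaluations); satisfies local accuracy
  φ0 + Σ_j φ_ij = f(x_i) to numerical precision.
* ``sampling`` — seeded Monte-Carlo over feature permutations with the same
  marginalization; unbiased for the exact values, with coalition-value
  caching so repeated prefixes cost one model call.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

MAX_EXACT_FEATURES = 12


def _as_predict(model):
    if callable(model) and not hasattr(model, "predict"):
        return lambda Z: np.asarray(model(Z), dtype=float)
    return lambda Z: np.asarray(model.predict(Z), dtype=float)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    return arr, [f"f{j}" for j in range(arr.shape[1])]


@dataclass
class ShapMatrix:
    """Per-record, per-feature attributions (in response units, here pKi)."""

    values: np.ndarray                  # (n_records, n_features)
    base_value: float                   # expected model output on background
    feature_names: list[str]
    method: str                         # "exact" or "sampling"
    n_samples: int | None = None
    seed: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def total(self) -> np.ndarray:
        """φ0 + Σ_j φ_ij per record — equals f(x_i) for the exact method."""
        return self.base_value + self.values.sum(axis=1)


def _coalition_values(
    predict, x: np.ndarray, background: np.ndarray, masks: list[int]
) -> dict[int, float]:
    """v(S) = mean over background rows of f(x on S, background elsewhere),
    evaluated for many coalitions per model call (batched for speed)."""
    d = x.size
    n_bg = background.shape[0]
    chunk_size = max(1, 200_000 // n_bg)
    out: dict[int, float] = {}
    for start in range(0, len(masks), chunk_size):
        chunk = masks[start : start + chunk_size]
        Z = np.tile(background, (len(chunk), 1))
        for ci, mask in enumerate(chunk):
            block = Z[ci * n_bg : (ci + 1) * n_bg]
            for j in range(d):
                if mask >> j & 1:
                    block[:, j] = x[j]
        means = predict(Z).reshape(len(chunk), n_bg).mean(axis=1)
        out.update(zip(chunk, (float(v) for v in means)))
    return out


def _exact_record(predict, background, x: np.ndarray) -> np.ndarray:
    d = x.size
    fact = [factorial(m) for m in range(d + 1)]
    v = _coalition_values(predict, x, background, list(range(1 << d)))
    phi = np.zeros(d)
    for mask in range(1 << d):
        size = bin(mask).count("1")
        weight = fact[size] * fact[d - size - 1] / fact[d]
        for j in range(d):
            if not mask >> j & 1:
                phi[j] += weight * (v[mask | 1 << j] - v[mask])
    return phi


def _sampling_record(
    predict, background, x: np.ndarray,
    n_samples: int, rng: np.random.Generator,
) -> np.ndarray:
    d = x.size
    orders = [rng.permutation(d) for _ in range(n_samples)]
    needed: set[int] = {0}
    for order in orders:
        mask = 0
        for j in order:
            mask |= 1 << int(j)
            needed.add(mask)
    v = _coalition_values(predict, x, background, sorted(needed))
    phi = np.zeros(d)
    for order in orders:
        mask = 0
        prev = v[0]
        for j in order:
            mask |= 1 << int(j)
            cur = v[mask]
            phi[j] += cur - prev
            prev = cur
    return phi / n_samples


def shap_values(
    model,
    X_background,
    X_explain,
    method: str = "auto",
    n_samples: int = 2000,
    seed: int = 0,
) -> ShapMatrix:
    """Shapley attributions for every record of ``X_explain``.

    ``method="auto"`` enumerates exactly up to 12 features and falls back to
    permutation sampling (``n_samples`` permutations per record) beyond that;
    requesting ``"exact"`` above the cap is refused with guidance rather than
    attempted.
    """
    predict = _as_predict(model)
    B, bg_names = _as_matrix(X_background)
    E, names = _as_matrix(X_explain)
    if B.shape[1] != E.shape[1]:
        raise ValueError("background and explain sets have different feature counts")
    if bg_names != names:
        raise ValueError("background and explain feature names differ")
    if B.shape[0] == 0:
        raise ValueError("background sample is empty")
    d = E.shape[1]
    if method == "auto":
        method = "exact" if d <= MAX_EXACT_FEATURES else "sampling"
    if method == "exact" and d > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration supports at most {MAX_EXACT_FEATURES} features "
            f"(got {d}); use method='sampling' with a permutation budget"
        )
    if method not in ("exact", "sampling"):
        raise ValueError(f"unknown method {method!r}")

    base = float(predict(B).mean())
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(E.shape[0]):
        x = E[i]
        if method == "exact":
            rows.append(_exact_record(predict, B, x))
        else:
            rows.append(_sampling_record(predict, B, x, n_samples, rng))
    return ShapMatrix(
        values=np.vstack(rows) if rows else np.empty((0, d)),
        base_value=base,
        feature_names=names,
        method=method,
        n_samples=n_samples if method == "sampling" else None,
        seed=seed if method == "sampling" else None,
    )


def background_sample(X, fraction: float = 0.1, seed: int = 0, min_rows: int = 1):
    """Seeded random background subset (default 10% of the dataset)."""
    n = len(X)
    k = max(min_rows, int(round(fraction * n)))
    idx = np.random.default_rng(seed).choice(n, size=min(k, n), replace=False)
    return X.iloc[sorted(idx)] if isinstance(X, pd.DataFrame) else np.asarray(X)[sorted(idx)]


def aggregate_importance(s: ShapMatrix) -> pd.DataFrame:
    """Features ranked by mean absolute attribution (descending, ties lexical),
    with the fraction of positive attributions as a sign-direction summary."""
    if s.values.size == 0:
        raise ValueError("empty attribution matrix")
    mean_abs = np.abs(s.values).mean(axis=0)
    frac_pos = (s.values > 0).mean(axis=0)
    out = pd.DataFrame({
        "feature": s.feature_names,
        "mean_abs_shap": mean_abs,
        "fraction_positive": frac_pos,
    })
    out = out.sort_values(
        ["mean_abs_shap", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def dependence_profile(s: ShapMatrix, feature: str, X_explain) -> pd.DataFrame:
    """Scatter-ready (feature value, attribution) pairs sorted by value."""
    if feature not in s.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    j = s.feature_names.index(feature)
    E, _ = _as_matrix(X_explain)
    out = pd.DataFrame({"value": E[:, j], "shap": s.values[:, j]})
    return out.sort_values("value", kind="mergesort").reset_index(drop=True)
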
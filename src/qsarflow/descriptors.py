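"""2D molecular descriptor computation and matrix preprocessing.

Descriptors are computed through a pluggable backend.  The default backend is
RDKit's full 2D descriptor list (~217 columns); the ``mordred`` backend, when
that package is installed, yields the full Mordred 2D set (1613 columns).
Only 2D descriptors are used, so values depend on the molecular graph alone
and never on a conformer.

Preprocessing follows the usual QSAR recipe, in this fixed order:
boolean→{0,1} encoding, per-column mean imputation of missing cells, then
removal of empty (all-missing) and constant (max == min) columns.  Encoding
comes first so a constant boolean column is still caught; imputation before
the constant test ensures all-missing columns are flagged as empty rather
than constant-after-fill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .records import StructureParseError, _parse_mol


class DescriptorBackendUnavailable(ImportError):
    """The requested descriptor backend is not installed."""


@dataclass
class DescriptorMatrix:
    """Compounds × named 2D descriptors; missing cells are NaN.

    ``frame`` is indexed by compound key with unique descriptor-name columns;
    boolean columns are kept as booleans until :func:`preprocess` encodes
    them.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValueError("descriptor names must be unique")

    @property
    def compound_keys(self) -> list:
        return list(self.frame.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.frame.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape


@dataclass
class PreprocessedMatrix(DescriptorMatrix):
    """Fully numeric descriptor matrix: no missing cells, no constants."""

    dropped: list[tuple[str, str]] = field(default_factory=list)
    imputation_means: dict[str, float] = field(default_factory=dict)


def _rdkit_descriptor_row(mol: Chem.Mol) -> dict[str, float]:
    # CalcMolDescriptors already maps per-descriptor failures to NaN
    return Descriptors.CalcMolDescriptors(mol, missingVal=float("nan"))


def _mordred_calculator():
    try:
        from mordred import Calculator, descriptors as mordred_descriptors
    except ImportError as exc:  # pragma: no cover - depends on optional extra
        raise DescriptorBackendUnavailable(
            "the 'mordred' descriptor backend requires the mordredcommunity "
            "package (pip install qsarflow[mordred]); the default 'rdkit' "
            "backend needs no extra dependency"
        ) from exc
    return Calculator(mordred_descriptors, ignore_3D=True)


def compute_2d_descriptors(
    structures: Sequence[str],
    backend: str = "rdkit",
    keys: Sequence[str] | None = None,
) -> DescriptorMatrix:
    """One descriptor row per structure; per-cell failures become NaN.

    Unparseable structures raise :class:`~qsarflow.records.StructureParseError`
    naming the offending string — callers are expected to filter first.
    """
    mols = [_parse_mol(s) for s in structures]
    index = list(keys) if keys is not None else list(range(len(mols)))
    if backend == "rdkit":
        rows = [_rdkit_descriptor_row(m) for m in mols]
        frame = pd.DataFrame(rows, index=index)
    elif backend == "mordred":
        calc = _mordred_calculator()
        frame = calc.pandas(mols, quiet=True)
        frame.index = index
        frame.columns = [str(c) for c in frame.columns]
        # mordred error objects -> missing
        frame = frame.map(
            lambda v: v if isinstance(v, (int, float, bool, np.integer, np.floating, np.bool_))
            else float("nan")
        )
    else:
        raise ValueError(f"unknown descriptor backend {backend!r}")
    return DescriptorMatrix(frame=frame)


def preprocess(
    m: DescriptorMatrix,
    *,
    means: dict[str, float] | None = None,
) -> PreprocessedMatrix:
    """Boolean-encode, mean-impute, then drop empty and constant columns.

    ``means`` overrides the imputation statistics (used by the fold-safe
    :class:`Preprocessor` so that cross-validation imputes held-out rows with
    training-fold means only); by default means come from the full matrix.
    """
    if m.frame.empty:
        raise ValueError("descriptor matrix is empty")
    frame = m.frame.copy()

    bool_cols = [c for c in frame.columns if frame[c].dtype == bool]
    for c in bool_cols:
        frame[c] = frame[c].astype(float)
    frame = frame.apply(pd.to_numeric, errors="coerce")

    dropped: list[tuple[str, str]] = []
    imputation_means: dict[str, float] = {}
    keep: list[str] = []
    for c in frame.columns:
        col = frame[c]
        observed = col.dropna()
        if observed.empty:
            dropped.append((c, "empty"))
            continue
        mu = float(means[c]) if means is not None and c in means else float(observed.mean())
        if col.isna().any():
            col = col.fillna(mu)
            imputation_means[c] = mu
        if float(col.max()) == float(col.min()):
            dropped.append((c, "constant"))
            imputation_means.pop(c, None)
            continue
        frame[c] = col
        keep.append(c)
    if not keep:
        raise ValueError("preprocessing removed every column (degenerate output)")
    return PreprocessedMatrix(
        frame=frame[keep].astype(float),
        dropped=dropped,
        imputation_means=imputation_means,
    )


class Preprocessor:
    """Fold-safe variant: learn imputation means on training rows only.

    ``fit`` records column means and the kept-column list from the training
    matrix; ``transform`` applies them to any matrix with the same columns,
    so cross-validation never leaks held-out statistics into the fit.
    """

    def __init__(self) -> None:
        self.means_: dict[str, float] | None = None
        self.columns_: list[str] | None = None

    def fit(self, m: DescriptorMatrix) -> "Preprocessor":
        pm = preprocess(m)
        numeric = m.frame.apply(pd.to_numeric, errors="coerce")
        self.means_ = {c: float(numeric[c].dropna().mean()) for c in pm.descriptor_names}
        self.columns_ = pm.descriptor_names
        return self

    def transform(self, m: DescriptorMatrix) -> PreprocessedMatrix:
        if self.means_ is None or self.columns_ is None:
            raise RuntimeError("Preprocessor.fit must be called first")
        frame = m.frame[self.columns_].copy()
        for c in frame.columns:
            if frame[c].dtype == bool:
                frame[c] = frame[c].astype(float)
        frame = frame.apply(pd.to_numeric, errors="coerce")
        frame = frame.fillna(pd.Series(self.means_))
        return PreprocessedMatrix(
            frame=frame.astype(float),
            dropped=[],
            imputation_means=dict(self.means_),
        )

    def fit_transform(self, m: DescriptorMatrix) -> PreprocessedMatrix:
        return self.fit(m).transform(m)


def write_matrix(m: DescriptorMatrix, y: Sequence[float], path: str | Path) -> None:
    """Tab-separated layout: descriptor columns then a final ``pKi`` column."""
    out = m.frame.copy()
    out["pKi"] = list(y)
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> tuple[DescriptorMatrix, np.ndarray]:
    """Read the tab-separated descriptor+pKi layout written by write_matrix."""
    frame = pd.read_csv(path, sep="\t")
    if "pKi" not in frame.columns:
        raise ValueError(f"{path}: expected a final pKi column")
    y = frame.pop("pKi").to_numpy(dtype=float)
    return DescriptorMatrix(frame=frame), y
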
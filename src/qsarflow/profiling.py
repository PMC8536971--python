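"""Exploratory profiling of a curated ligand database.

Covers the standard medicinal-chemistry screens and summaries:

* Lipinski's rule of five (MW < 500 Da, logP < 5, H-bond donors ≤ 5,
  H-bond acceptors ≤ 10) and the Veber oral-bioavailability rules
  (topological PSA ≤ 140 Å², rotatable bonds < 10);
* pairwise Tanimoto similarity |A∩B|/|A∪B| on fingerprint bit sets, with a
  seeded pair-sampling fallback for large libraries;
* pKi summary statistics and a Pearson correlation matrix over named
  descriptor columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .records import _parse_mol

#: descriptor-matrix columns feeding the rules, in Mordred naming
RULE_COLUMNS_MORDRED = {
    "mw": "MW", "slogp": "SLogP", "hbd": "nHBDon",
    "hba": "nHBAcc", "psa": "TopoPSA", "nrot": "nRot",
}
#: the same quantities in RDKit descriptor naming
RULE_COLUMNS_RDKIT = {
    "mw": "MolWt", "slogp": "MolLogP", "hbd": "NumHDonors",
    "hba": "NumHAcceptors", "psa": "TPSA", "nrot": "NumRotatableBonds",
}


@dataclass(frozen=True)
class RuleFlags:
    """Per-compound drug-likeness flags."""

    mw_ok: bool
    logp_ok: bool
    hbd_ok: bool
    hba_ok: bool
    psa_ok: bool
    rot_ok: bool

    @property
    def lipinski_ok(self) -> bool:
        return self.mw_ok and self.logp_ok and self.hbd_ok and self.hba_ok

    @property
    def veber_ok(self) -> bool:
        return self.psa_ok and self.rot_ok


def lipinski_veber(
    mw: float, slogp: float, hbd: int, hba: int, psa: float, nrot: int
) -> RuleFlags:
    """Evaluate both rule sets for one compound.

    MW and rotatable-bond limits are strict (< 500, < 10); donor, acceptor
    and PSA limits are inclusive (≤ 5, ≤ 10, ≤ 140).
    """
    if mw < 0 or psa < 0 or hbd < 0 or hba < 0 or nrot < 0:
        raise ValueError("counts, MW and PSA must be nonnegative")
    return RuleFlags(
        mw_ok=mw < 500.0,
        logp_ok=slogp < 5.0,
        hbd_ok=hbd <= 5,
        hba_ok=hba <= 10,
        psa_ok=psa <= 140.0,
        rot_ok=nrot < 10,
    )


def rule_report(
    frame: pd.DataFrame, columns: dict[str, str] = RULE_COLUMNS_MORDRED
) -> dict:
    """Aggregate rule percentages over a descriptor table.

    ``columns`` maps the roles mw/slogp/hbd/hba/psa/nrot to column names
    (defaults to the Mordred names; use :data:`RULE_COLUMNS_RDKIT` for the
    RDKit backend).  Returns counts and percentages per rule plus the two
    composite rules.
    """
    missing = [c for c in columns.values() if c not in frame.columns]
    if missing:
        raise KeyError(f"descriptor table lacks rule columns: {missing}")
    flags = pd.DataFrame({
        "mw_ok": frame[columns["mw"]] < 500.0,
        "logp_ok": frame[columns["slogp"]] < 5.0,
        "hbd_ok": frame[columns["hbd"]] <= 5,
        "hba_ok": frame[columns["hba"]] <= 10,
        "psa_ok": frame[columns["psa"]] <= 140.0,
        "rot_ok": frame[columns["nrot"]] < 10,
    })
    flags["lipinski_ok"] = flags[["mw_ok", "logp_ok", "hbd_ok", "hba_ok"]].all(axis=1)
    flags["veber_ok"] = flags[["psa_ok", "rot_ok"]].all(axis=1)
    n = len(flags)
    report = {"n": n, "flags": flags}
    for col in flags.columns:
        count = int(flags[col].sum())
        report[col] = {"count": count, "percent": round(100.0 * count / n, 2)}
    return report


def morgan_fingerprints(
    structures: Sequence[str], radius: int = 2, n_bits: int = 2048
):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return [gen.GetFingerprint(_parse_mol(s)) for s in structures]


def tanimoto(fp_a, fp_b) -> float:
    """|A∩B| / |A∪B| for bit sets or RDKit explicit bit vectors."""
    if isinstance(fp_a, (set, frozenset)) or isinstance(fp_b, (set, frozenset)):
        a, b = set(fp_a), set(fp_b)
        union = a | b
        if not union:
            raise ValueError("Tanimoto undefined for two empty fingerprints")
        return len(a & b) / len(union)
    if fp_a.GetNumOnBits() == 0 and fp_b.GetNumOnBits() == 0:
        raise ValueError("Tanimoto undefined for two empty fingerprints")
    return DataStructs.TanimotoSimilarity(fp_a, fp_b)


@dataclass
class SimilaritySummary:
    values: np.ndarray
    min: float
    median: float
    max: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    fingerprint: str
    sampled: bool

    def as_dict(self) -> dict:
        return {
            "min": self.min, "median": self.median, "max": self.max,
            "n_pairs": int(self.values.size), "fingerprint": self.fingerprint,
            "sampled": self.sampled,
        }


def similarity_summary(
    structures: Sequence[str],
    *,
    radius: int = 2,
    n_bits: int = 2048,
    max_exact: int = 2000,
    sample_pairs: int = 1_000_000,
    n_hist_bins: int = 20,
    seed: int = 0,
) -> SimilaritySummary:
    """Pairwise Tanimoto distribution over a structure library.

    All pairs are evaluated exactly up to ``max_exact`` structures
    (n(n−1)/2 grows quadratically); above that, ``sample_pairs`` distinct
    random pairs are drawn with the given seed.
    """
    n = len(structures)
    if n < 2:
        raise ValueError("similarity summary needs at least 2 structures")
    fps = morgan_fingerprints(structures, radius=radius, n_bits=n_bits)
    sampled = n > max_exact
    values: list[float] = []
    if not sampled:
        for i in range(n):
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
            values.extend(sims)
    else:
        rng = np.random.default_rng(seed)
        total = n * (n - 1) // 2
        k = min(sample_pairs, total)
        flat = rng.choice(total, size=k, replace=False)
        # map flat upper-triangle index -> (i, j)
        i_idx = (n - 2 - np.floor(
            np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2.0 - 0.5)).astype(int)
        j_idx = (flat + i_idx + 1 - i_idx * (2 * n - i_idx - 1) // 2).astype(int)
        values = [
            DataStructs.TanimotoSimilarity(fps[i], fps[j])
            for i, j in zip(i_idx.tolist(), j_idx.tolist())
        ]
    arr = np.asarray(values, dtype=float)
    counts, edges = np.histogram(arr, bins=n_hist_bins, range=(0.0, 1.0))
    return SimilaritySummary(
        values=arr,
        min=float(arr.min()),
        median=float(np.median(arr)),
        max=float(arr.max()),
        hist_counts=counts,
        hist_edges=edges,
        fingerprint=f"morgan r={radius} {n_bits} bits",
        sampled=sampled,
    )


def pki_summary(pki: Sequence[float]) -> dict:
    arr = np.asarray(pki, dtype=float)
    return {
        "n": int(arr.size),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "median": float(np.median(arr)),
    }


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame
    undefined: list[str] = field(default_factory=list)


def correlation_matrix(frame: pd.DataFrame) -> CorrelationResult:
    """Symmetric Pearson correlation matrix over named numeric columns.

    Zero-variance columns make a correlation undefined; they are reported in
    ``undefined`` and their rows/columns set to NaN explicitly rather than
    propagating silently.
    """
    if len(frame) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    degenerate = [c for c in frame.columns if float(frame[c].std(ddof=0)) == 0.0]
    corr = frame.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = np.nan
    return CorrelationResult(matrix=corr, undefined=degenerate)
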
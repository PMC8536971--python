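"""Synthetic test-bed generators with known ground truth.

Three generators give every pipeline stage a controllable input:

* :func:`gen_smiles_library` — valid, diverse SMILES assembled from a small
  fragment grammar (aryl rings, piperazines/piperidines, alkyl linkers,
  carbonyls, halogens) echoing the arylpiperazine-like chemotypes typical of
  serotonin-receptor ligand sets.
* :func:`gen_sources` — a pair of overlapping bioactivity sources with a
  configured number of shared structures and of discordant duplicate pKi
  pairs, so the curation arithmetic can be checked against a closed form.
* :func:`gen_qsar_dataset` — descriptor-like feature matrices with a known
  (optionally nonlinear) feature→pKi function plus Gaussian noise, for
  model-recovery and feature-selection benchmarks.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .records import RecordSet, canonical_key, record_set_from_pairs

PKI_CLIP = (4.2, 11.0)
#: largest |ΔpKi| drawn for discordant cross-source duplicates
MAX_DISCORDANT_DELTA = 4.46

# -- fragment grammar ---------------------------------------------------------
# Head-to-tail fragments: each starts with an atom and may be concatenated.
# Ring fragments open and close their ring digit internally, so plain string
# concatenation always yields syntactically valid SMILES; chemically invalid
# assemblies are caught by RDKit and rejection-sampled away.
_EXTENDERS = [
    "C", "CC", "CCC",
    "OC", "NC",
    "C(=O)", "C(=O)N", "C(=O)O",
    "c1ccccc1", "c1cc(F)ccc1", "c1ccncc1", "c1ccsc1",
    "N1CCN(CC1)", "C1CCN(CC1)",
]
_TERMINALS = ["", "C", "O", "N", "F", "Cl", "Br", "C#N", "C(F)(F)F", "OC"]


def _assemble(rng: np.random.Generator) -> str:
    n_units = int(rng.integers(2, 7))
    parts = [_EXTENDERS[int(rng.integers(len(_EXTENDERS)))] for _ in range(n_units)]
    parts.append(_TERMINALS[int(rng.integers(len(_TERMINALS)))])
    return "".join(parts)


def gen_smiles_library(n: int, seed: int = 0) -> list[str]:
    """``n`` distinct, valid, canonical SMILES from the fragment grammar.

    Distinctness is enforced at generation time by rejection sampling on the
    canonical structure key, so every output re-canonicalizes to itself.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError("fragment grammar exhausted; cannot reach n distinct")
        candidate = _assemble(rng)
        try:
            key = canonical_key(candidate)
        except ValueError:
            continue
        if key in seen:
            continue
        seen.add(key)
        out.append(key)
    return out


# -- paired overlapping sources ----------------------------------------------

@dataclass(frozen=True)
class SourcePairSpec:
    """Blueprint for two overlapping bioactivity sources.

    ``n_a``/``n_b`` are per-source unique compound counts, ``n_shared`` of
    which occur in both sources; ``n_discordant`` of the shared structures get
    a |ΔpKi| strictly above ``threshold`` (drawn up to 4.46 log units, the
    upper end seen in real two-source merges), the rest stay within it.
    """

    n_a: int
    n_b: int
    n_shared: int
    n_discordant: int
    threshold: float = 0.1
    pki_mean: float = 7.0
    pki_sd: float = 1.0
    clip: tuple[float, float] = PKI_CLIP
    seed: int = 0
    source_a: str = "ZINC"
    source_b: str = "ChEMBL"

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_a, self.n_b):
            raise ValueError("n_shared must not exceed min(n_a, n_b)")
        if self.n_discordant > self.n_shared:
            raise ValueError("n_discordant must not exceed n_shared")
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")
        if self.n_discordant and self.threshold > 2.0:
            raise ValueError("discordant deltas need threshold <= 2.0 inside the pKi clip range")

    @property
    def expected_final(self) -> int:
        """Closed-form post-curation count: n_a + n_b − n_shared − n_discordant."""
        return self.n_a + self.n_b - self.n_shared - self.n_discordant


def _clipped_normal(rng, n, mean, sd, clip):
    return np.clip(rng.normal(mean, sd, size=n), clip[0], clip[1])


def _offset_within(rng, base: float, delta: float, clip) -> float:
    """base ± delta, choosing a sign that stays inside the clip range."""
    lo, hi = clip
    up_ok = base + delta <= hi
    down_ok = base - delta >= lo
    if up_ok and down_ok:
        sign = 1.0 if rng.random() < 0.5 else -1.0
    elif up_ok:
        sign = 1.0
    elif down_ok:
        sign = -1.0
    else:  # unreachable for delta <= (hi - lo) / 2
        raise ValueError(f"delta {delta} does not fit the clip range around {base}")
    return base + sign * delta


def gen_sources(
    spec: SourcePairSpec, *, structure_mode: str = "smiles"
) -> tuple[RecordSet, RecordSet, dict]:
    """Two record sets with exactly the configured overlap, plus ground truth.

    ``structure_mode="smiles"`` (default) draws real structures from the
    fragment grammar; ``"token"`` uses opaque distinct keys, which is faster
    when only the curation arithmetic is under test.
    """
    rng = np.random.default_rng(spec.seed)
    n_structures = spec.n_a + spec.n_b - spec.n_shared
    if structure_mode == "smiles":
        structures = gen_smiles_library(n_structures, seed=spec.seed)
        keyed = True  # library outputs are already canonical keys
    elif structure_mode == "token":
        structures = [f"STRUCT-{spec.seed}-{i:07d}" for i in range(n_structures)]
        keyed = True
    else:
        raise ValueError(f"unknown structure_mode {structure_mode!r}")

    shared = structures[: spec.n_shared]
    a_only = structures[spec.n_shared : spec.n_a]
    b_only = structures[spec.n_a :]

    a_structs = shared + a_only
    pki_a = _clipped_normal(rng, spec.n_a, spec.pki_mean, spec.pki_sd, spec.clip)
    a_pairs = list(zip(a_structs, pki_a))

    # shared structures reappear in source b with a controlled |ΔpKi|
    discordant_idx = set(
        rng.choice(spec.n_shared, size=spec.n_discordant, replace=False).tolist()
    ) if spec.n_discordant else set()
    delta_hi = min(MAX_DISCORDANT_DELTA, (spec.clip[1] - spec.clip[0]) / 2)
    b_pairs: list[tuple[str, float]] = []
    for i, struct in enumerate(shared):
        base = float(pki_a[i])
        if i in discordant_idx:
            u = 1.0 - rng.random()  # (0, 1]: delta strictly above threshold
            delta = spec.threshold + u * (delta_hi - spec.threshold)
        else:
            delta = rng.random() * min(spec.threshold, delta_hi)
        b_pairs.append((struct, _offset_within(rng, base, delta, spec.clip)))
    pki_b_only = _clipped_normal(rng, len(b_only), spec.pki_mean, spec.pki_sd, spec.clip)
    b_pairs.extend(zip(b_only, pki_b_only))

    a = record_set_from_pairs(spec.source_a, a_pairs, keyed=keyed)
    b = record_set_from_pairs(spec.source_b, b_pairs, keyed=keyed)
    truth = {
        "n_a": spec.n_a,
        "n_b": spec.n_b,
        "n_shared": spec.n_shared,
        "n_discordant": spec.n_discordant,
        "expected_final": spec.expected_final,
        "shared_keys": shared,
        "discordant_keys": [shared[i] for i in sorted(discordant_idx)],
    }
    return a, b, truth


# -- regression benchmarks ----------------------------------------------------

@dataclass(frozen=True)
class QsarBenchSpec:
    """Descriptor-matrix regression benchmark with known generative truth."""

    n: int = 2000
    d: int = 50
    k: int = 5
    form: str = "additive-nonlinear"  # linear | additive-nonlinear | interaction
    noise_sd: float = 0.5
    clip: tuple[float, float] = PKI_CLIP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.d:
            raise ValueError("k must not exceed d")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.form not in ("linear", "additive-nonlinear", "interaction"):
            raise ValueError(f"unknown functional form {self.form!r}")


_NONLIN: list[Callable[[np.ndarray], np.ndarray]] = [
    lambda x: np.sin(2.0 * x),
    lambda x: x**2,
    lambda x: np.tanh(2.0 * x),
    lambda x: np.abs(x),
]


def gen_qsar_dataset(spec: QsarBenchSpec) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Standard-normal features with y = rescaled f(informative) + noise.

    The raw signal f is standardized and mapped to pKi scale (mean 7, sd 1),
    then Gaussian noise of ``noise_sd`` is added and the result clipped to the
    pKi range.  The returned truth dict includes the informative column names
    and the noiseless clipped response for oracle checks.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.d))
    names = [f"x{i + 1:03d}" for i in range(spec.d)]
    informative = names[: spec.k]
    # each component is standardized to unit variance before its amplitude is
    # applied, so amplitudes in [1, 2] directly bound the per-feature share of
    # signal variance: every informative feature genuinely carries signal
    amps = rng.uniform(1.0, 2.0, size=spec.k) * rng.choice([-1.0, 1.0], size=spec.k)

    def _unit(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std()

    if spec.form == "linear":
        f = sum(amps[j] * _unit(X[:, j]) for j in range(spec.k))
        shapes: list[str] = ["identity"] * spec.k
    else:
        shape_idx = rng.integers(len(_NONLIN), size=spec.k)
        shapes = [f"g{int(j)}" for j in shape_idx]
        f = np.zeros(spec.n)
        for j in range(spec.k):
            f += amps[j] * _unit(_NONLIN[int(shape_idx[j])](X[:, j]))
        if spec.form == "interaction":
            for j in range(spec.k - 1):
                f += 0.5 * _unit(X[:, j] * X[:, j + 1])

    z = (f - f.mean()) / f.std()
    y0 = np.clip(7.0 + z, spec.clip[0], spec.clip[1])
    y = np.clip(y0 + rng.normal(0.0, spec.noise_sd, size=spec.n), *spec.clip)
    if spec.noise_sd == 0:
        y = y0.copy()

    frame = pd.DataFrame(X, columns=names)
    truth = {
        "informative": informative,
        "amplitudes": amps.tolist(),
        "shapes": shapes,
        "form": spec.form,
        "noiseless_y": y0,
    }
    return frame, y, truth
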
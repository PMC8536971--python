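"""Ligand bioactivity records: the data model and I/O shared by the whole pipeline.

A record couples one source's measurement of a compound's affinity for the
receptor — expressed as pKi, the negative decadic logarithm of the inhibition
constant Ki in molar units — with the compound structure as SMILES.  Every
downstream stage identifies compounds by ``structure_key``, a canonical
identity string, so that the same molecule written with different atom
orderings (or as a salt) collapses to one entity.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: pKi values outside this range are chemically implausible (Ki of 1 M down to
#: 1e-14 M); the loader flags them as suspect but never drops them itself.
PKI_PLAUSIBLE_RANGE = (0.0, 14.0)


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class EmptyInputError(ValueError):
    """Raised when an input file yields zero parseable records."""


@dataclass(frozen=True)
class BioactivityRecord:
    """One source's pKi measurement for one compound."""

    record_id: str
    source_id: str
    structure: str
    structure_key: str
    pKi: float

    def __post_init__(self) -> None:
        lo, hi = PKI_PLAUSIBLE_RANGE
        if not (self.pKi == self.pKi and abs(self.pKi) != float("inf")):
            raise ValueError(f"pKi must be finite, got {self.pKi!r}")
        if not lo <= self.pKi <= hi:
            warnings.warn(
                f"record {self.record_id}: pKi={self.pKi} outside plausible "
                f"range {PKI_PLAUSIBLE_RANGE}; kept (curation decides removal)",
                stacklevel=2,
            )


@dataclass
class RejectedRow:
    """A row the loader could not turn into a record, with the reason."""

    row_number: int
    reason: str
    payload: str = ""


@dataclass
class RecordSet:
    """Ordered collection of records sharing one source label."""

    source_id: str
    records: list[BioactivityRecord] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record_id values must be unique within a RecordSet")
        for r in self.records:
            if r.source_id != self.source_id:
                raise ValueError(
                    f"record {r.record_id} carries source {r.source_id!r}, "
                    f"set is {self.source_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BioactivityRecord]:
        return iter(self.records)

    def keys(self) -> set[str]:
        return {r.structure_key for r in self.records}

    def by_key(self) -> dict[str, list[BioactivityRecord]]:
        out: dict[str, list[BioactivityRecord]] = {}
        for r in self.records:
            out.setdefault(r.structure_key, []).append(r)
        return out


def _parse_mol(structure: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureParseError(f"unparseable SMILES: {structure!r}")
    return mol


def canonical_key(
    structure: str,
    *,
    stereo: bool = True,
    strip_salts: bool = True,
    neutralize: bool = True,
) -> str:
    """Canonical identity string for a structure.

    Canonical SMILES with stereochemistry retained by default, so that
    stereoisomers coexist as distinct database entries; ``stereo=False``
    gives a stereo-agnostic key.  Salt stripping keeps the largest organic
    fragment and ``neutralize`` removes formal charges where possible; both
    can be switched off for sources that are already standardized.
    Idempotent: re-keying a key returns the same key.
    """
    mol = _parse_mol(structure)
    if strip_salts and len(Chem.GetMolFrags(mol)) > 1:
        mol = rdMolStandardize.FragmentParent(mol)
    if neutralize:
        mol = rdMolStandardize.Uncharger().uncharge(mol)
    if not stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol, canonical=True)


def _coerce_pki(raw: str, *, from_ki_molar: bool = False) -> float:
    import math

    value = float(raw)
    if from_ki_molar:
        if value <= 0:
            raise ValueError(f"Ki must be positive to convert, got {value}")
        value = -math.log10(value)
    if not math.isfinite(value):
        raise ValueError(f"non-finite pKi {raw!r}")
    return value


def _make_record(
    source_id: str,
    index: int,
    smiles: str,
    pki_raw: str,
    *,
    key_kwargs: dict,
    from_ki_molar: bool,
) -> BioactivityRecord:
    key = canonical_key(smiles, **key_kwargs)
    pki = _coerce_pki(pki_raw, from_ki_molar=from_ki_molar)
    return BioactivityRecord(
        record_id=f"{source_id}-{index}",
        source_id=source_id,
        structure=smiles,
        structure_key=key,
        pKi=pki,
    )


def load_records(
    path: str | Path,
    format: str = "csv",
    source_id: str = "unknown",
    *,
    smiles_col: str = "smiles",
    pki_col: str = "pKi",
    from_ki_molar: bool = False,
    stereo: bool = True,
    strip_salts: bool = True,
    neutralize: bool = True,
) -> RecordSet:
    """Load a record set from ``csv``, ``smi`` or ``sdf``.

    Rows with an unparseable structure or non-numeric activity are collected
    in :attr:`RecordSet.rejects` with a reason — counted and logged, never
    silently dropped.  Raises :class:`EmptyInputError` if nothing parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    key_kwargs = dict(stereo=stereo, strip_salts=strip_salts, neutralize=neutralize)
    records: list[BioactivityRecord] = []
    rejects: list[RejectedRow] = []

    def try_add(i: int, smiles: str, pki_raw: str, payload: str) -> None:
        try:
            records.append(
                _make_record(
                    source_id, i, smiles, pki_raw,
                    key_kwargs=key_kwargs, from_ki_molar=from_ki_molar,
                )
            )
        except (StructureParseError, ValueError) as exc:
            rejects.append(RejectedRow(i, str(exc), payload))

    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise EmptyInputError(f"{path}: no header row")
            for col in (smiles_col, pki_col):
                if col not in reader.fieldnames:
                    raise ValueError(f"{path}: missing column {col!r}")
            for i, row in enumerate(reader):
                try_add(i, row[smiles_col], row[pki_col], str(row))
    elif format == "smi":
        # one structure per line, optional tab-separated id then pKi
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split("\t")
                if not parts or not parts[0]:
                    continue
                pki_raw = parts[-1] if len(parts) > 1 else "nan"
                try_add(i, parts[0], pki_raw, line.strip())
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                rejects.append(RejectedRow(i, "unparseable SDF molblock"))
                continue
            pki_raw = mol.GetProp(pki_col) if mol.HasProp(pki_col) else "nan"
            try_add(i, Chem.MolToSmiles(mol), pki_raw, f"sdf entry {i}")
    else:
        raise ValueError(f"unknown format {format!r}")

    if not records:
        raise EmptyInputError(f"{path}: zero parseable records ({len(rejects)} rejected)")
    if rejects:
        logger.info("%s: rejected %d rows", path, len(rejects))
    return RecordSet(source_id=source_id, records=records, rejects=rejects)


def write_records(rs: RecordSet, path: str | Path) -> None:
    """Write a record set as UTF-8 CSV (columns: smiles, pKi, source, key)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "pKi", "source", "structure_key"])
        for r in rs.records:
            writer.writerow([r.structure, repr(r.pKi), r.source_id, r.structure_key])


def record_set_from_pairs(
    source_id: str, pairs: Iterable[tuple[str, float]], *, keyed: bool = False
) -> RecordSet:
    """Build a RecordSet from (smiles, pKi) pairs; with ``keyed=True`` the
    first element is taken as a pre-computed structure key (no parsing)."""
    records = []
    for i, (smi, pki) in enumerate(pairs):
        key = smi if keyed else canonical_key(smi)
        records.append(
            BioactivityRecord(
                record_id=f"{source_id}-{i}", source_id=source_id,
                structure=smi, structure_key=key, pKi=float(pki),
            )
        )
    return RecordSet(source_id=source_id, records=records)
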
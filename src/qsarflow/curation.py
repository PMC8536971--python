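"""Two-source database curation: deduplication, merging, conflict resolution.

The procedure mirrors the standard bioactivity-curation workflow for building
a single structure→pKi table out of two overlapping sources:

1. deduplicate within each source (concordant repeats are averaged,
   discordant ones removed);
2. pool the sources and find structures present in both;
3. for each cross-source pair, compare the two pKi values: if they differ by
   more than a threshold (default 0.1 log units) the compound is considered
   unreliable and BOTH measurements are discarded; otherwise the measurement
   from the designated priority source is kept.

Every count is tracked in an audit object so the arithmetic
``final = |a| + |b| − pairs − discordant_pairs`` can be verified.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from statistics import mean, median
from typing import Iterable

from .records import BioactivityRecord, RecordSet

DEFAULT_THRESHOLD = 0.1


@dataclass(frozen=True)
class DuplicatePair:
    """A structure measured by both sources; ``record_a`` is the priority side."""

    record_a: BioactivityRecord
    record_b: BioactivityRecord

    def __post_init__(self) -> None:
        if self.record_a.structure_key != self.record_b.structure_key:
            raise ValueError("pair members must share a structure_key")

    @property
    def delta_pKi(self) -> float:
        return abs(self.record_a.pKi - self.record_b.pKi)


@dataclass
class CurationAudit:
    """Bookkeeping for every stage of the merge."""

    uniques_a: int = 0
    uniques_b: int = 0
    pooled_total: int = 0
    duplicate_records: int = 0
    pairs_total: int = 0
    pairs_kept: int = 0
    pairs_dropped: int = 0
    final_uniques: int = 0
    threshold: float = DEFAULT_THRESHOLD
    priority: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CuratedEntry:
    structure_key: str
    smiles: str
    pKi: float
    source: str


@dataclass
class CuratedDatabase:
    """Deduplicated structure→pKi map with provenance and audit counts."""

    entries: dict[str, CuratedEntry] = field(default_factory=dict)
    audit: CurationAudit = field(default_factory=CurationAudit)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def to_rows(self) -> list[CuratedEntry]:
        return list(self.entries.values())

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["structure_key", "smiles", "pKi", "source"])
            for e in self.entries.values():
                w.writerow([e.structure_key, e.smiles, repr(e.pKi), e.source])

    def write_audit(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.audit.as_dict(), indent=2, sort_keys=True))


def dedupe_within_source(
    rs: RecordSet,
    threshold: float = DEFAULT_THRESHOLD,
    policy: str = "consistent",
) -> RecordSet:
    """Collapse same-structure repeats inside one source.

    Groups whose pKi spread (max − min) is within ``threshold`` collapse to
    the arithmetic mean; wider groups are removed entirely under the default
    ``"consistent"`` policy, or collapsed to the median under ``"median"``.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if policy not in ("consistent", "median"):
        raise ValueError(f"unknown policy {policy!r}")
    out: list[BioactivityRecord] = []
    for key, group in rs.by_key().items():
        if len(group) == 1:
            out.append(group[0])
            continue
        values = [r.pKi for r in group]
        spread = max(values) - min(values)
        if spread <= threshold:
            collapsed = mean(values)
        elif policy == "median":
            collapsed = median(values)
        else:
            continue  # discordant group dropped wholesale
        first = group[0]
        out.append(
            BioactivityRecord(
                record_id=first.record_id,
                source_id=first.source_id,
                structure=first.structure,
                structure_key=key,
                pKi=collapsed,
            )
        )
    return RecordSet(source_id=rs.source_id, records=out)


def _require_deduped(rs: RecordSet, label: str) -> dict[str, BioactivityRecord]:
    groups = rs.by_key()
    offending = sorted(k for k, g in groups.items() if len(g) > 1)
    if offending:
        raise ValueError(
            f"RecordSet {label!r} is not deduplicated; offending keys: "
            + ", ".join(offending[:10])
            + ("..." if len(offending) > 10 else "")
        )
    return {k: g[0] for k, g in groups.items()}


def find_cross_pairs(a: RecordSet, b: RecordSet) -> list[DuplicatePair]:
    """One pair per structure present in both (already deduplicated) sources."""
    map_a = _require_deduped(a, a.source_id)
    map_b = _require_deduped(b, b.source_id)
    shared = sorted(map_a.keys() & map_b.keys())
    return [DuplicatePair(map_a[k], map_b[k]) for k in shared]


def resolve_duplicates(
    a: RecordSet,
    b: RecordSet,
    threshold: float = DEFAULT_THRESHOLD,
    priority: str | None = None,
) -> CuratedDatabase:
    """Merge two deduplicated sources into a curated database.

    For each cross-source pair: |ΔpKi| > ``threshold`` removes both members;
    |ΔpKi| ≤ ``threshold`` (boundary inclusive) keeps the priority source's
    value.  Unpaired records pass through unchanged.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    priority = a.source_id if priority is None else priority
    if priority not in (a.source_id, b.source_id):
        raise ValueError(f"priority {priority!r} names neither source")
    if priority == b.source_id:
        a, b = b, a

    map_a = _require_deduped(a, a.source_id)
    map_b = _require_deduped(b, b.source_id)
    pairs = find_cross_pairs(a, b)

    audit = CurationAudit(
        uniques_a=len(map_a),
        uniques_b=len(map_b),
        pooled_total=len(map_a) + len(map_b),
        duplicate_records=2 * len(pairs),
        pairs_total=len(pairs),
        threshold=threshold,
        priority=priority,
    )

    entries: dict[str, CuratedEntry] = {}
    discordant_keys = set()
    for p in pairs:
        if p.delta_pKi > threshold:
            discordant_keys.add(p.record_a.structure_key)
            audit.pairs_dropped += 1
        else:
            audit.pairs_kept += 1

    paired_keys = {p.record_a.structure_key for p in pairs}
    for key, rec in map_a.items():
        if key in discordant_keys:
            continue
        entries[key] = CuratedEntry(key, rec.structure, rec.pKi, rec.source_id)
    for key, rec in map_b.items():
        if key in paired_keys:
            continue  # concordant → priority member already in; discordant → dropped
        entries[key] = CuratedEntry(key, rec.structure, rec.pKi, rec.source_id)

    audit.final_uniques = len(entries)
    expected = audit.pooled_total - audit.pairs_total - audit.pairs_dropped
    assert audit.final_uniques == expected, "curation count invariant violated"
    return CuratedDatabase(entries=entries, audit=audit)
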
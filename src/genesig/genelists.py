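"""Standardization of heterogeneous published gene lists into a common
GeneID space.

Published differential-expression lists come keyed by probe codes, symbols
or platform-specific identifiers. This module converts them — via a
user-supplied, offline, many-to-many mapping table — into :class:`GeneList`
objects keyed by GeneID, with per-gene direction annotations (up / down /
unspecified), and implements the probe-call aggregation rule used for
five-level present/absent call matrices.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "unspecified")

#: Permitted call scores: Increase, Marginal Increase, No Change,
#: Marginal Decrease, Decrease.
CALL_VALUES = {"I": 1.1, "MI": 1.0, "NC": 0.0, "MD": -1.0, "D": -1.1}
_PERMITTED_SCORES = frozenset(CALL_VALUES.values())


def _validate_direction(direction: str) -> str:
    if direction not in DIRECTIONS:
        raise ValueError(
            f"direction must be one of {DIRECTIONS}, got {direction!r}"
        )
    return direction


@dataclass(frozen=True)
class GeneID:
    """A gene identifier token; exact string equality, never empty."""

    value: str

    def __post_init__(self) -> None:
        trimmed = self.value.strip()
        if not trimmed:
            raise ValueError("GeneID must be non-empty after trimming")
        object.__setattr__(self, "value", trimmed)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


@dataclass(frozen=True)
class GeneRecord:
    """One gene in a list: identifier, direction, and the original label."""

    id: GeneID
    direction: str = "unspecified"
    source_label: str = ""

    def __post_init__(self) -> None:
        _validate_direction(self.direction)


@dataclass
class GeneList:
    """A named set of :class:`GeneRecord`, unique by GeneID."""

    name: str
    records: dict[str, GeneRecord] = field(default_factory=dict)
    sample_type: str = ""
    provenance: str = ""

    @classmethod
    def from_records(
        cls,
        name: str,
        records: Iterable[GeneRecord],
        sample_type: str = "",
        provenance: str = "",
    ) -> "GeneList":
        out = cls(name=name, sample_type=sample_type, provenance=provenance)
        for rec in records:
            if rec.id.value in out.records:
                raise ValueError(f"duplicate GeneID {rec.id.value!r} in list {name!r}")
            out.records[rec.id.value] = rec
        return out

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __iter__(self):
        return iter(self.records.values())


@dataclass
class IDMappingTable:
    """Many-to-many source identifier → GeneID mapping (case-sensitive)."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "IDMappingTable":
        build: dict[str, set[str]] = {}
        for src, gid in pairs:
            src = src.strip()
            gid = gid.strip()
            if not src or not gid:
                raise ValueError("mapping rows must have non-empty source and gene_id")
            build.setdefault(src, set()).add(gid)
        return cls({k: frozenset(v) for k, v in build.items()})

    @classmethod
    def identity(cls, identifiers: Iterable[str]) -> "IDMappingTable":
        """Map each identifier to itself (lists already keyed by GeneID)."""
        return cls({s.strip(): frozenset({s.strip()}) for s in identifiers})

    def lookup(self, source_id: str) -> frozenset[str]:
        return self.entries.get(source_id, frozenset())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class StandardizationReport:
    """Per-list accounting of what the mapping did."""

    list_name: str
    input_count: int
    mapped: int
    dropped: int
    fanout: int
    direction_conflicts: int
    unmapped_ids: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "list_name": self.list_name,
            "input_count": self.input_count,
            "mapped": self.mapped,
            "dropped": self.dropped,
            "fanout": self.fanout,
            "direction_conflicts": self.direction_conflicts,
            "unmapped_ids": sorted(self.unmapped_ids),
        }


def standardize_list(
    raw_entries: Sequence[tuple[str, str]],
    mapping: IDMappingTable,
    name: str,
    sample_type: str = "",
    provenance: str = "",
) -> tuple[GeneList, StandardizationReport]:
    """Convert (source identifier, direction) pairs into a GeneList.

    Every source identifier fans out to all of its mapped GeneIDs; unmapped
    identifiers are dropped (and reported, never guessed); duplicate GeneIDs
    collapse by set semantics. When the same GeneID is reached from both an
    up- and a down-annotated source, the collapsed record's direction is
    ``unspecified`` and a warning is logged — excluding it silently would
    bias downstream overlap counts.

    Returns the list together with a :class:`StandardizationReport`.
    """
    if not raw_entries:
        raise ValueError("raw_entries is empty")
    if len(mapping) == 0:
        raise ValueError("mapping table is empty")

    directions_seen: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    mapped = dropped = fanout = 0
    unmapped: list[str] = []
    for source_id, direction in raw_entries:
        _validate_direction(direction)
        targets = mapping.lookup(source_id)
        if not targets:
            dropped += 1
            unmapped.append(source_id)
            continue
        mapped += 1
        if len(targets) > 1:
            fanout += 1
        for gid in targets:
            directions_seen.setdefault(gid, set()).add(direction)
            labels.setdefault(gid, source_id)

    conflicts = 0
    records = {}
    for gid, dirs in directions_seen.items():
        explicit = dirs - {"unspecified"}
        if len(explicit) == 1:
            direction = next(iter(explicit))
        elif len(explicit) > 1:
            conflicts += 1
            direction = "unspecified"
            logger.warning(
                "list %r: GeneID %s reached from conflicting directions %s; "
                "marked unspecified",
                name, gid, sorted(explicit),
            )
        else:
            direction = "unspecified"
        records[gid] = GeneRecord(GeneID(gid), direction, labels[gid])

    gene_list = GeneList(
        name=name,
        records=records,
        sample_type=sample_type,
        provenance=provenance,
    )
    report = StandardizationReport(
        list_name=name,
        input_count=len(raw_entries),
        mapped=mapped,
        dropped=dropped,
        fanout=fanout,
        direction_conflicts=conflicts,
        unmapped_ids=unmapped,
    )
    return gene_list, report


def aggregate_call_scores(
    matrix: pd.DataFrame,
    up_threshold: float = 5.5,
    down_threshold: float = -5.5,
) -> dict[str, str]:
    """Sum five-level call scores across comparison columns per probe.

    Cells must be one of {1.1, 1.0, 0.0, -1.0, -1.1} (the I/MI/NC/MD/D
    scores). A probe whose row sum is strictly greater than ``up_threshold``
    is called ``up``; strictly less than ``down_threshold``, ``down``;
    otherwise ``unchanged``. Comparisons are strict (>, <) exactly.
    """
    if not down_threshold < up_threshold:
        raise ValueError(
            f"down_threshold ({down_threshold}) must be < up_threshold ({up_threshold})"
        )
    for probe, row in matrix.iterrows():
        for col, value in row.items():
            if float(value) not in _PERMITTED_SCORES:
                raise ValueError(
                    f"probe {probe!r}, column {col!r}: call score {value!r} "
                    f"not one of {sorted(_PERMITTED_SCORES)}"
                )
    sums = matrix.astype(float).sum(axis=1)
    out: dict[str, str] = {}
    for probe, total in sums.items():
        if total > up_threshold:
            out[str(probe)] = "up"
        elif total < down_threshold:
            out[str(probe)] = "down"
        else:
            out[str(probe)] = "unchanged"
    return out


def split_directions(gene_list: GeneList) -> tuple[GeneList, GeneList]:
    """Partition a list into its up- and down-annotated records.

    Unspecified records appear in neither half.
    """
    up = GeneList.from_records(
        f"{gene_list.name}_up",
        (r for r in gene_list if r.direction == "up"),
        sample_type=gene_list.sample_type,
        provenance=gene_list.provenance,
    )
    down = GeneList.from_records(
        f"{gene_list.name}_down",
        (r for r in gene_list if r.direction == "down"),
        sample_type=gene_list.sample_type,
        provenance=gene_list.provenance,
    )
    return up, down


def union_size(*lists: GeneList) -> int:
    """Number of unique GeneIDs across the given lists."""
    ids: set[str] = set()
    for gl in lists:
        ids |= gl.ids
    return len(ids)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a gene list from 2-column TSV (gene_id, direction) or 1-column.

    Lines starting with ``#`` are comments; a header row is detected when
    the second field of the first row is not a valid direction token.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if rows and len(rows[0]) >= 2 and rows[0][1].strip().lower() not in DIRECTIONS:
        rows = rows[1:]  # header
    seen: set[str] = set()
    for row in rows:
        gid = row[0].strip()
        direction = row[1].strip().lower() if len(row) > 1 and row[1].strip() else "unspecified"
        if gid in seen:
            continue
        seen.add(gid)
        records.append(GeneRecord(GeneID(gid), _validate_direction(direction)))
    return GeneList.from_records(name or path.stem, records)


def write_gene_list(gene_list: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdirection\n")
        for rec in sorted(gene_list, key=lambda r: r.id.value):
            fh.write(f"{rec.id.value}\t{rec.direction}\n")


def read_mapping_table(path: str | Path) -> IDMappingTable:
    """Read a 2-column TSV (source_id, gene_id); repeated rows = many-to-many."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i + 1} has fewer than 2 columns")
            if i == 0 and parts[0].strip().lower() in {"source_id", "source", "probe"}:
                continue
            pairs.append((parts[0], parts[1]))
    return IDMappingTable.from_pairs(pairs)


def read_gmt(path: str | Path) -> list[GeneList]:
    """Read GMT: one set per line (name, description, genes...). Directions
    are not representable in GMT and load as ``unspecified``."""
    lists: list[GeneList] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line needs >= 3 fields: {line!r}")
            name, description = parts[0], parts[1]
            records = [
                GeneRecord(GeneID(g)) for g in dict.fromkeys(p for p in parts[2:] if p.strip())
            ]
            lists.append(GeneList.from_records(name, records, provenance=description))
    return lists


def write_gmt(lists: Sequence[GeneList], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# GMT export: direction annotations are not representable "
                 "in GMT and are lost\n")
        for gl in lists:
            genes = "\t".join(sorted(gl.ids))
            fh.write(f"{gl.name}\t{gl.provenance or 'na'}\t{genes}\n")


def read_call_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe × comparison call matrix from CSV.

    Cells may be the literal tokens I/MI/NC/MD/D or their numeric scores.
    """
    df = pd.read_csv(path, index_col=0)
    df = df.map(lambda v: CALL_VALUES.get(str(v).strip(), v))
    return df.astype(float)


def direction_counts(gene_list: GeneList) -> Counter:
    return Counter(rec.direction for rec in gene_list)
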
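"""Rank-based multi-category tumour-signature scoring.

Each marker gene carries, per category, a sign (+1 up / −1 down) and a
positive integer rank R. The category coefficient is C = 1/HR, HR being the
highest rank in that category, and a gene whose observed direction matches
its sign contributes B = 1 − C·R to the category score; a gene whose
direction is the strict opposite contributes B to the complement
("not-category") score; unchanged or absent genes contribute to neither.
Raw scores are normalized by the score of the "ideal" profile (every gene
matching its sign), so an ideal profile scores exactly 1 and a fully
non-matching one 0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

_SIGN_TO_DIRECTION = {1: "up", -1: "down"}
_OPPOSITE = {"up": "down", "down": "up"}

#: Default relative-score threshold above which a profile is considered
#: diagnosable as the category.
DIAGNOSIS_THRESHOLD = 0.4


@dataclass(frozen=True)
class ScoringEntry:
    """One (gene, category) marker: sign ∈ {+1, −1} and rank ≥ 1."""

    gene: str
    category: str
    sign: int
    rank: int
    specific_category: str | None = None

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if not (isinstance(self.rank, int) and self.rank >= 1):
            raise ValueError(f"rank must be a positive integer, got {self.rank!r}")
        if not self.gene.strip():
            raise ValueError("gene label must be non-empty")


@dataclass
class ScoringTable:
    """The scorer's sole parameterization: signed, ranked marker entries."""

    entries: list[ScoringEntry]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.gene, e.category)
            if key in seen:
                raise ValueError(f"duplicate (gene, category) pair {key}")
            seen.add(key)
        if not self.categories:
            raise ValueError("scoring table has no entries")

    @property
    def categories(self) -> list[str]:
        return sorted({e.category for e in self.entries})

    def entries_for(self, category: str) -> list[ScoringEntry]:
        out = [e for e in self.entries if e.category == category]
        if not out:
            raise ValueError(f"category {category!r} has no entries")
        return out

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(e.gene for e in self.entries)

    def specificity_map(self) -> dict[str, str]:
        """gene → the single category the gene is specific to.

        Taken from the explicit ``specific_category`` column when present;
        a gene with entries in exactly one category and no explicit value
        defaults to that category; ambiguous genes are omitted.
        """
        explicit: dict[str, str] = {}
        categories_per_gene: dict[str, set[str]] = {}
        for e in self.entries:
            categories_per_gene.setdefault(e.gene, set()).add(e.category)
            if e.specific_category:
                prev = explicit.get(e.gene)
                if prev is not None and prev != e.specific_category:
                    raise ValueError(
                        f"gene {e.gene!r} has conflicting specific_category values"
                    )
                explicit[e.gene] = e.specific_category
        out = dict(explicit)
        for gene, cats in categories_per_gene.items():
            if gene not in out and len(cats) == 1:
                out[gene] = next(iter(cats))
        return out


@dataclass
class DirectionProfile:
    """gene → direction ∈ {up, down, unchanged} for one sample/contrast."""

    directions: dict[str, str]

    def __post_init__(self) -> None:
        for gene, direction in self.directions.items():
            if direction not in ("up", "down", "unchanged"):
                raise ValueError(
                    f"gene {gene!r}: bad direction {direction!r}"
                )

    def get(self, gene: str) -> str:
        return self.directions.get(gene, "unchanged")

    def __len__(self) -> int:
        return len(self.directions)


@dataclass
class CategoryScore:
    raw: float
    raw_complement: float
    ideal: float
    relative: float
    relative_complement: float
    diagnosable: bool


@dataclass
class ScoreReport:
    """Raw, ideal and relative scores per category plus settings echo."""

    scores: dict[str, CategoryScore]
    threshold: float
    ignored_genes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "ignored_genes": sorted(self.ignored_genes),
            "categories": {
                cat: {
                    "raw": s.raw,
                    "raw_complement": s.raw_complement,
                    "ideal": round(s.ideal, 6),
                    "relative": s.relative,
                    "relative_complement": s.relative_complement,
                    "diagnosable": s.diagnosable,
                }
                for cat, s in self.scores.items()
            },
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    def write_radar_csv(self, path: str | Path) -> None:
        """Tabular stand-in for the radar chart: one spoke per category."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["category", "relative", "relative_complement", "diagnosable"]
            )
            for cat in sorted(self.scores):
                s = self.scores[cat]
                writer.writerow(
                    [cat, f"{s.relative:.6f}", f"{s.relative_complement:.6f}",
                     str(s.diagnosable).lower()]
                )


def compute_coefficients(table: ScoringTable) -> dict[str, float]:
    """Per category, C = 1 / highest rank. Full precision; round only when
    reporting (6 decimals is the conventional display)."""
    return {
        cat: 1.0 / max(e.rank for e in table.entries_for(cat))
        for cat in table.categories
    }


def gene_contribution(matches_sign: bool, C: float, R: int) -> float:
    """B = 1 − C·R when the observed direction matches the sign, else 0."""
    if R < 1:
        raise ValueError(f"rank must be >= 1, got {R}")
    if not 0 < C <= 1:
        raise ValueError(f"coefficient must be in (0, 1], got {C}")
    if C * R > 1 + 1e-12:
        raise ValueError(f"C*R = {C * R} > 1: rank exceeds category maximum")
    if not matches_sign:
        return 0.0
    return 1.0 - C * R


def ideal_scores(table: ScoringTable) -> dict[str, float]:
    """Score of the ideal profile per category: Σ (1 − C·R).

    The complement's ideal equals the category's (every entry flips from
    matching to opposite when the profile is inverted).
    """
    coeffs = compute_coefficients(table)
    return {
        cat: sum(
            gene_contribution(True, coeffs[cat], e.rank)
            for e in table.entries_for(cat)
        )
        for cat in table.categories
    }


def score_profile(
    profile: DirectionProfile,
    table: ScoringTable,
    threshold: float = DIAGNOSIS_THRESHOLD,
) -> ScoreReport:
    """Score a direction profile against every category of the table.

    Per category: raw S sums B over entries whose profile direction equals
    the entry's sign; the complement score sums B over entries whose
    direction is the strict opposite; unchanged or absent genes add 0 to
    both. Relative scores divide by the ideal score (0 when the ideal is 0).
    Profile genes absent from the table are ignored and listed in the
    report.
    """
    coeffs = compute_coefficients(table)
    ideals = ideal_scores(table)
    scores: dict[str, CategoryScore] = {}
    for cat in table.categories:
        raw = raw_not = 0.0
        for e in table.entries_for(cat):
            direction = profile.get(e.gene)
            expected = _SIGN_TO_DIRECTION[e.sign]
            b = gene_contribution(True, coeffs[cat], e.rank)
            if direction == expected:
                raw += b
            elif direction == _OPPOSITE[expected]:
                raw_not += b
        ideal = ideals[cat]
        relative = raw / ideal if ideal > 0 else 0.0
        relative_not = raw_not / ideal if ideal > 0 else 0.0
        scores[cat] = CategoryScore(
            raw=raw,
            raw_complement=raw_not,
            ideal=ideal,
            relative=relative,
            relative_complement=relative_not,
            diagnosable=relative >= threshold,
        )
    ignored = sorted(set(profile.directions) - table.genes)
    return ScoreReport(scores=scores, threshold=threshold, ignored_genes=ignored)


def classify(
    report: ScoreReport, threshold: float = DIAGNOSIS_THRESHOLD
) -> dict[str, bool]:
    """Per-category diagnosable flag: relative score ≥ threshold."""
    flags = {}
    for cat, s in report.scores.items():
        if not 0.0 <= s.relative <= 1.0 + 1e-12:
            raise ValueError(f"relative score out of [0, 1] for {cat!r}")
        flags[cat] = s.relative >= threshold
    return flags


def count_category_hits(
    genes: Iterable[str], table: ScoringTable
) -> dict[str, int]:
    """Count, per category, how many input genes are specific to it.

    Genes absent from the specificity map count under ``unassigned``.
    """
    spec = table.specificity_map()
    counts: dict[str, int] = {cat: 0 for cat in table.categories}
    counts["unassigned"] = 0
    for gene in genes:
        cat = spec.get(gene, "unassigned")
        counts[cat] = counts.get(cat, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_scoring_table(path: str | Path) -> ScoringTable:
    """TSV columns: gene, category, sign (+1/-1), rank[, specific_category]."""
    entries: list[ScoringEntry] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() == "gene":
                continue  # header
            if len(row) < 4:
                raise ValueError(f"{path}: row {i + 1} has fewer than 4 columns")
            specific = row[4].strip() if len(row) > 4 and row[4].strip() else None
            entries.append(
                ScoringEntry(
                    gene=row[0].strip(),
                    category=row[1].strip(),
                    sign=int(row[2]),
                    rank=int(row[3]),
                    specific_category=specific,
                )
            )
    return ScoringTable(entries)


def write_scoring_table(table: ScoringTable, path: str | Path,
                        header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene\tcategory\tsign\trank\tspecific_category\n")
        for e in table.entries:
            sign = f"{e.sign:+d}"
            fh.write(
                f"{e.gene}\t{e.category}\t{sign}\t{e.rank}\t"
                f"{e.specific_category or ''}\n"
            )


def read_profile(path: str | Path) -> DirectionProfile:
    """2-column TSV: gene, direction ∈ {up, down, unchanged}."""
    directions: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].strip().lower() == "gene":
                continue  # header
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i + 1} has fewer than 2 columns")
            gene = parts[0].strip()
            if gene in directions:
                raise ValueError(f"{path}: duplicate gene {gene!r}")
            directions[gene] = parts[1].strip().lower()
    return DirectionProfile(directions)


def write_profile(profile: DirectionProfile, path: str | Path,
                  header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene\tdirection\n")
        for gene in sorted(profile.directions):
            fh.write(f"{gene}\t{profile.directions[gene]}\n")
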
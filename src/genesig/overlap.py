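"""Intersection sizes and hypergeometric tail probabilities for gene-list
pairs against a finite universe, and the many-vs-many significance matrix.

The tail statistic is the probability of observing, by chance, an
intersection at least as large as the one seen when two lists of sizes
``n1`` and ``n2`` are drawn without replacement from a universe of ``N``
genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from genesig.genelists import GeneList

GRADES = ("ns", "*", "**", "***")


@dataclass
class Universe:
    """The finite gene universe a test conditions on.

    Either a bare size (membership unchecked) or an explicit member set
    (then ``size == len(members)`` and tested lists must be subsets).
    """

    size: int
    members: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.members is not None:
            self.members = frozenset(self.members)
            if self.size != len(self.members):
                raise ValueError(
                    f"universe size {self.size} != |members| {len(self.members)}"
                )
        if self.size <= 0:
            raise ValueError("universe size must be positive")

    @classmethod
    def from_members(cls, members: Iterable[str]) -> "Universe":
        members = frozenset(members)
        return cls(size=len(members), members=members)

    @classmethod
    def from_lists(cls, lists: Iterable[GeneList], padding: int = 0) -> "Universe":
        """Universe as the union of the given lists plus optional extra size
        standing in for unlisted platform genes (membership then unchecked)."""
        union: set[str] = set()
        for gl in lists:
            union |= gl.ids
        if padding:
            return cls(size=len(union) + padding)
        return cls.from_members(union)

    def check_list(self, gene_list: GeneList) -> None:
        if len(gene_list) > self.size:
            raise ValueError(
                f"list {gene_list.name!r} has {len(gene_list)} genes "
                f"> universe size {self.size}"
            )
        if self.members is not None and not gene_list.ids <= self.members:
            missing = sorted(gene_list.ids - self.members)[:5]
            raise ValueError(
                f"list {gene_list.name!r} is not a subset of the universe "
                f"(e.g. {missing})"
            )


@dataclass
class OverlapResult:
    k: int
    n1: int
    n2: int
    N: int
    p_value: float
    shared: frozenset[str]
    grade: str

    def __post_init__(self) -> None:
        if len(self.shared) != self.k:
            raise ValueError("|shared| must equal k")
        if not 0 <= self.k <= min(self.n1, self.n2):
            raise ValueError("k must lie in [0, min(n1, n2)]")

    def cell(self) -> str:
        """Compact export form, e.g. ``30***`` or ``6 (ns)``."""
        return f"{self.k} (ns)" if self.grade == "ns" else f"{self.k}{self.grade}"

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "n1": self.n1,
            "n2": self.n2,
            "N": self.N,
            "p_value": self.p_value,
            "grade": self.grade,
            "shared": sorted(self.shared),
        }


def intersect(a: GeneList, b: GeneList) -> frozenset[str]:
    """Exact, direction-agnostic GeneID set intersection (symmetric)."""
    return frozenset(a.ids & b.ids)


def hypergeom_tail(N: int, K: int, n: int, k: int, strict: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the marked genes among ``n`` drawn without replacement from a
    population of ``N`` containing ``K`` marked. With ``strict=True``
    returns P(X > k) instead. Computed in log space via scipy for
    numerical safety.
    """
    if not 0 <= k:
        raise ValueError(f"k must be >= 0, got k={k}")
    if not k <= min(K, n):
        raise ValueError(f"k <= min(K, n) violated: k={k}, K={K}, n={n}")
    if not max(K, n) <= N:
        raise ValueError(f"max(K, n) <= N violated: K={K}, n={n}, N={N}")
    if k < max(0, K + n - N):
        raise ValueError(
            f"k >= max(0, K + n - N) violated: k={k}, K+n-N={K + n - N}"
        )
    # sf(k-1) = P(X >= k); sf(k) = P(X > k)
    p = float(hypergeom.sf(k - (0 if strict else 1), N, K, n))
    return min(p, 1.0)


def grade_significance(p: float) -> str:
    """Star grade: p < 0.001 → ***, < 0.01 → **, < 0.05 → *, else ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def overlap_test(
    a: GeneList,
    b: GeneList,
    universe: Universe,
    strict: bool = False,
) -> OverlapResult:
    """Test the overlap of two lists against the hypergeometric null."""
    universe.check_list(a)
    universe.check_list(b)
    shared = intersect(a, b)
    k = len(shared)
    p = hypergeom_tail(universe.size, len(a), len(b), k, strict=strict)
    return OverlapResult(
        k=k,
        n1=len(a),
        n2=len(b),
        N=universe.size,
        p_value=p,
        shared=shared,
        grade=grade_significance(p),
    )


def _bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = min(prev, pvalues[i] * m / rank_from_top)
        adjusted[i] = q
        prev = q
    return adjusted


@dataclass
class OverlapMatrix:
    """Complete rectangular grid of overlap tests (rows × columns)."""

    row_names: list[str]
    col_names: list[str]
    cells: dict[tuple[str, str], OverlapResult]
    universe: Universe
    stratify: str = "all"
    bh_adjusted: dict[tuple[str, str], float] | None = None

    def __getitem__(self, key: tuple[str, str]) -> OverlapResult:
        return self.cells[key]

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.col_names)]
        for r in self.row_names:
            row = [r] + [self.cells[(r, c)].cell() for c in self.col_names]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def as_dict(self) -> dict:
        out = {
            "universe": {
                "size": self.universe.size,
                "explicit_membership": self.universe.members is not None,
            },
            "stratify": self.stratify,
            "rows": self.row_names,
            "columns": self.col_names,
            "cells": {
                f"{r}|{c}": self.cells[(r, c)].as_dict()
                for r in self.row_names
                for c in self.col_names
            },
        }
        if self.bh_adjusted is not None:
            out["bh_adjusted"] = {
                f"{r}|{c}": q for (r, c), q in self.bh_adjusted.items()
            }
        return out

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        Path(tsv_path).write_text(self.to_tsv())
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def overlap_matrix(
    row_lists: Sequence[GeneList],
    col_lists: Sequence[GeneList],
    universe: Universe,
    strict: bool = False,
    bh: bool = False,
) -> OverlapMatrix:
    """Test every (row, column) pair of lists against the same universe.

    ``bh=True`` additionally reports Benjamini–Hochberg adjusted p-values
    across all cells (grades stay raw, matching the tabular convention).
    """
    if not row_lists or not col_lists:
        raise ValueError("both list collections must be non-empty")
    cells: dict[tuple[str, str], OverlapResult] = {}
    for a in row_lists:
        for b in col_lists:
            cells[(a.name, b.name)] = overlap_test(a, b, universe, strict=strict)
    matrix = OverlapMatrix(
        row_names=[gl.name for gl in row_lists],
        col_names=[gl.name for gl in col_lists],
        cells=cells,
        universe=universe,
    )
    if bh:
        keys = list(cells)
        adjusted = _bh_adjust([cells[key].p_value for key in keys])
        matrix.bh_adjusted = dict(zip(keys, adjusted))
    return matrix


def stratified_overlap_matrices(
    row_lists: Sequence[GeneList],
    col_lists: Sequence[GeneList],
    universe: Universe,
    strict: bool = False,
) -> dict[str, OverlapMatrix]:
    """Direction-stratified matrices: up∩up and down∩down separately."""
    from genesig.genelists import split_directions

    out: dict[str, OverlapMatrix] = {}
    for which, idx in (("up", 0), ("down", 1)):
        rows = [split_directions(gl)[idx] for gl in row_lists]
        cols = [split_directions(gl)[idx] for gl in col_lists]
        m = overlap_matrix(rows, cols, universe, strict=strict)
        m.stratify = which
        out[which] = m
    return out
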
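"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of an explicit integer seed (one
`numpy.random.default_rng` per call — no global state), so a fixed config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from genesig.ddct import CtMatrix
from genesig.genelists import GeneID, GeneList, GeneRecord
from genesig.tumor_score import DirectionProfile, ScoringEntry, ScoringTable

_SIGN_TO_DIRECTION = {1: "up", -1: "down"}
_OPPOSITE = {"up": "down", "down": "up"}


@dataclass
class SimConfig:
    """Parameters for all generators; unused fields are ignored per call."""

    seed: int = 0
    # overlap / list-pair generation
    universe_size: int = 1000
    n1: int = 100
    n2: int = 100
    forced_overlap: int | None = None  # None => draw under the null
    # scoring-table generation
    categories: tuple[str, ...] = ("EWS", "RMS", "NB", "BL")
    genes_per_category: int = 24
    max_rank: int = 100
    # profile generation
    match_fraction: float = 1.0
    # Ct-matrix generation
    n_genes: int = 10
    n_per_group: int = 6
    group_shift: float = -1.0  # cycles added to the case group's dCt
    noise_sd: float = 0.3
    affected_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.universe_size <= 0 or self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("sizes must be positive")
        if max(self.n1, self.n2) > self.universe_size:
            raise ValueError("list sizes must not exceed the universe size")
        if self.forced_overlap is not None:
            k = self.forced_overlap
            if not 0 <= k <= min(self.n1, self.n2):
                raise ValueError(f"forced overlap {k} not in [0, min(n1, n2)]")
            if self.n1 + self.n2 - k > self.universe_size:
                raise ValueError(
                    "forced overlap infeasible: n1 + n2 - k exceeds the universe"
                )
        if not 0.0 <= self.match_fraction <= 1.0:
            raise ValueError("match_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "categories" in data:
            data["categories"] = tuple(data["categories"])
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_comment(self) -> str:
        return f"seed={self.seed} config_digest={self.digest()}"


def _universe_labels(n: int) -> list[str]:
    return [f"g{i + 1}" for i in range(n)]


def gen_list_pair(config: SimConfig) -> tuple[GeneList, GeneList]:
    """Two lists from the universe {g1..gN}.

    With ``forced_overlap=k`` the intersection is exactly k; with
    ``forced_overlap=None`` both lists are independent uniform draws
    without replacement (the hypergeometric null).
    """
    rng = np.random.default_rng(config.seed)
    universe = np.array(_universe_labels(config.universe_size))
    if config.forced_overlap is None:
        ids_a = rng.choice(universe, size=config.n1, replace=False)
        ids_b = rng.choice(universe, size=config.n2, replace=False)
    else:
        k = config.forced_overlap
        pool = rng.permutation(universe)
        shared = pool[:k]
        rest = pool[k:]
        ids_a = np.concatenate([shared, rest[: config.n1 - k]])
        ids_b = np.concatenate([shared, rest[config.n1 - k: config.n1 - k + config.n2 - k]])
    make = lambda name, ids: GeneList.from_records(
        name,
        (GeneRecord(GeneID(str(g))) for g in ids),
        provenance=f"synthetic {config.header_comment()}",
    )
    return make("sim_a", ids_a), make("sim_b", ids_b)


def gen_scoring_table(config: SimConfig) -> ScoringTable:
    """Random scoring table: per category, distinct ranks from 1..max_rank
    with the maximum always present (so HR = max_rank), random ±1 signs."""
    if config.genes_per_category < 1:
        raise ValueError("genes_per_category must be >= 1")
    if config.genes_per_category > config.max_rank:
        raise ValueError("genes_per_category cannot exceed max_rank")
    rng = np.random.default_rng(config.seed)
    entries: list[ScoringEntry] = []
    gene_counter = 0
    for cat in config.categories:
        lower = rng.choice(
            np.arange(1, config.max_rank),
            size=config.genes_per_category - 1,
            replace=False,
        )
        ranks = sorted(int(r) for r in lower) + [config.max_rank]
        for rank in ranks:
            gene_counter += 1
            sign = int(rng.choice([1, -1]))
            entries.append(
                ScoringEntry(
                    gene=f"m{gene_counter}",
                    category=cat,
                    sign=sign,
                    rank=rank,
                    specific_category=cat,
                )
            )
    return ScoringTable(entries)


def gen_profile_with_match(
    table: ScoringTable,
    category: str,
    match_fraction: float,
    seed: int,
) -> DirectionProfile:
    """Profile in which a controlled fraction of one category's entries
    match their signs.

    ``round(f*n)`` entries (ties toward more matches) get the direction of
    their sign, the remainder the opposite direction; genes of all other
    categories are set unchanged.
    """
    if not 0.0 <= match_fraction <= 1.0:
        raise ValueError("match_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    entries = table.entries_for(category)
    n_match = int(np.floor(match_fraction * len(entries) + 0.5))
    idx = rng.permutation(len(entries))
    matched = set(idx[:n_match].tolist())
    directions: dict[str, str] = {
        e.gene: "unchanged" for e in table.entries if e.category != category
    }
    for i, e in enumerate(entries):
        expected = _SIGN_TO_DIRECTION[e.sign]
        directions[e.gene] = expected if i in matched else _OPPOSITE[expected]
    return DirectionProfile(directions)


def gen_ct_dataset(
    config: SimConfig, shifts: Mapping[str, float] | None = None
) -> CtMatrix:
    """Ct matrix with a planted case-vs-control ΔCt shift.

    One reference gene REF with Ct ~ Normal(20, sd); each target gene gets
    a baseline ΔCt (uniform in [2, 10]) plus, for the affected genes in the
    case group, ``group_shift`` cycles; Gaussian measurement noise on every
    target Ct. Groups are labelled ``control`` and ``case``.

    ``shifts`` optionally plants an explicit per-gene case-group ΔCt shift
    (the gene labels then come from the mapping), overriding the uniform
    ``group_shift`` / ``affected_fraction`` scheme.
    """
    rng = np.random.default_rng(config.seed)
    if shifts is None:
        genes = [f"t{i + 1}" for i in range(config.n_genes)]
        n_affected = int(np.floor(config.affected_fraction * config.n_genes + 0.5))
        gene_shifts = {
            g: (config.group_shift if i < n_affected else 0.0)
            for i, g in enumerate(genes)
        }
    else:
        genes = list(shifts)
        gene_shifts = dict(shifts)
    samples = [f"ctrl_{i + 1}" for i in range(config.n_per_group)] + [
        f"case_{i + 1}" for i in range(config.n_per_group)
    ]
    groups = {s: ("control" if s.startswith("ctrl") else "case") for s in samples}
    case_mask = np.array([groups[s] == "case" for s in samples])

    ref_ct = rng.normal(20.0, config.noise_sd, size=len(samples))
    baselines = rng.uniform(2.0, 10.0, size=len(genes))
    rows = {"REF": ref_ct}
    for gi, gene in enumerate(genes):
        dct_true = np.full(len(samples), baselines[gi])
        dct_true[case_mask] += gene_shifts[gene]
        noise = rng.normal(0.0, config.noise_sd, size=len(samples))
        rows[gene] = ref_ct + dct_true + noise
    values = pd.DataFrame(rows, index=samples).T
    return CtMatrix(
        values=values,
        sample_groups=groups,
        reference_genes=frozenset({"REF"}),
    )


def gen_ct_for_profile(
    table: ScoringTable,
    category: str,
    match_fraction: float,
    config: SimConfig,
    shift_cycles: float = 2.0,
) -> tuple[CtMatrix, DirectionProfile]:
    """Ct dataset whose planted effects realize a controlled match fraction.

    Entries of ``category`` chosen to match get a ΔCt shift in the
    direction of their sign (−shift for +1/up, +shift for −1/down); the
    rest get the opposite shift; genes of other categories get no shift.
    Returns the matrix together with the intended direction profile.
    """
    intended = gen_profile_with_match(table, category, match_fraction, config.seed)
    shifts: dict[str, float] = {}
    for gene, direction in intended.directions.items():
        if direction == "up":
            shifts[gene] = -abs(shift_cycles)
        elif direction == "down":
            shifts[gene] = abs(shift_cycles)
        else:
            shifts[gene] = 0.0
    return gen_ct_dataset(config, shifts=shifts), intended
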
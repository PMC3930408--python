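"""Relative quantification of qPCR Ct matrices (ddCt) and per-gene
significance calls.

Pipeline: per-sample reference normalization (ΔCt), group-mean calibration
(ΔΔCt, fold change 2^−ΔΔCt), one-way ANOVA on ΔCt values across subject
groups, and thresholded direction calls that feed the signature scorer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from genesig.tumor_score import DirectionProfile


@dataclass
class CtMatrix:
    """Gene × sample Ct table with group labels and reference genes.

    ``values`` holds threshold-cycle measurements (NaN = undetermined /
    no amplification). Every sample must carry a group label; every
    reference gene must have a finite Ct in every sample.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    reference_genes: frozenset[str]

    def __post_init__(self) -> None:
        self.reference_genes = frozenset(self.reference_genes)
        if not self.reference_genes:
            raise ValueError("at least one reference gene is required")
        missing_genes = self.reference_genes - set(self.values.index)
        if missing_genes:
            raise ValueError(f"reference genes absent from matrix: {sorted(missing_genes)}")
        unlabelled = set(self.values.columns) - set(self.sample_groups)
        if unlabelled:
            raise ValueError(f"samples without a group label: {sorted(unlabelled)}")
        ref_block = self.values.loc[sorted(self.reference_genes)]
        if ref_block.isna().any().any():
            bad = ref_block.columns[ref_block.isna().any()].tolist()
            raise ValueError(f"reference gene Ct missing in samples: {bad}")

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.values.index if g not in self.reference_genes]

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.sample_groups.values()))

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]


@dataclass
class ExpressionCall:
    gene: str
    rq: float
    p_value: float
    direction: str

    def __post_init__(self) -> None:
        if not self.rq > 0:
            raise ValueError(f"rq must be positive, got {self.rq}")
        if self.direction not in ("up", "down", "unchanged"):
            raise ValueError(f"bad direction {self.direction!r}")


def delta_ct(ct_target: float, ct_reference: float | Sequence[float]) -> float:
    """ΔCt = target Ct − reference Ct.

    With several reference genes their arithmetic-mean Ct is used.
    """
    if isinstance(ct_reference, (int, float)):
        refs = [float(ct_reference)]
    else:
        refs = [float(r) for r in ct_reference]
    if not refs or any(not math.isfinite(r) for r in refs):
        raise ValueError("reference Ct measurements must be finite and non-empty")
    if not math.isfinite(ct_target):
        raise ValueError("target Ct must be finite")
    return float(ct_target) - sum(refs) / len(refs)


def relative_quantity(dct_sample: float, dct_calibrator: float) -> float:
    """rq = 2^−ΔΔCt with ΔΔCt = ΔCt_sample − ΔCt_calibrator."""
    if not (math.isfinite(dct_sample) and math.isfinite(dct_calibrator)):
        raise ValueError("ΔCt values must be finite")
    return float(2.0 ** -(dct_sample - dct_calibrator))


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, upper-tail p).

    Requires at least two groups of at least two observations each.
    Identical group means give F = 0, p = 1; zero within-group variance
    with distinct means is degenerate and raises.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    if any(not np.all(np.isfinite(a)) for a in arrays):
        raise ValueError("observations must be finite")
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1 = len(arrays) - 1
    df2 = len(allv) - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise ValueError("all observations identical: ANOVA undefined")
        raise ValueError("zero within-group variance: ANOVA degenerate")
    f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(f_dist.sf(f_stat, df1, df2))
    return float(f_stat), p


def call_differential(
    rq: float,
    p: float,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> str:
    """Direction call from fold change and significance.

    up if rq ≥ fc_threshold and p < alpha; down if rq ≤ 1/fc_threshold and
    p < alpha; otherwise unchanged.
    """
    if not rq > 0:
        raise ValueError("rq must be positive")
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if p < alpha and rq >= fc_threshold:
        return "up"
    if p < alpha and rq <= 1.0 / fc_threshold:
        return "down"
    return "unchanged"


def profile_from_calls(calls: Sequence[ExpressionCall]) -> DirectionProfile:
    """Collapse per-gene calls into the scorer's direction profile."""
    directions: dict[str, str] = {}
    for call in calls:
        if call.gene in directions:
            raise ValueError(f"duplicate gene {call.gene!r} in calls")
        directions[call.gene] = call.direction
    return DirectionProfile(directions)


@dataclass
class DdctResult:
    calls: list[ExpressionCall]
    excluded: list[str]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.gene, c.rq, c.p_value, c.direction) for c in self.calls],
            columns=["gene", "rq", "p_value", "direction"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def profile(self) -> DirectionProfile:
        return profile_from_calls(self.calls)


def analyze_ct_matrix(
    matrix: CtMatrix,
    control_group: str,
    case_group: str | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    max_missing: float = 0.2,
) -> DdctResult:
    """Full ddCt analysis of a Ct matrix.

    ΔCt per sample uses the arithmetic-mean reference Ct; the calibrator is
    the mean ΔCt of the control group; fold change for each target gene is
    2^−ΔΔCt of the case group; one-way ANOVA runs on ΔCt values across all
    groups. Genes with more than ``max_missing`` of their Ct values
    undetermined are excluded (reported in ``excluded``).
    """
    groups = matrix.groups
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in {groups}")
    if case_group is None:
        others = [g for g in groups if g != control_group]
        if len(others) != 1:
            raise ValueError(
                "case_group must be given explicitly when there are "
                f"{len(others)} non-control groups"
            )
        case_group = others[0]
    if case_group not in groups:
        raise ValueError(f"case group {case_group!r} not in {groups}")

    ref_mean = matrix.values.loc[sorted(matrix.reference_genes)].mean(axis=0)
    dct = matrix.values.loc[matrix.target_genes].sub(ref_mean, axis=1)

    control_samples = matrix.samples_in(control_group)
    case_samples = matrix.samples_in(case_group)
    calls: list[ExpressionCall] = []
    excluded: list[str] = []
    for gene in matrix.target_genes:
        row = dct.loc[gene]
        if row.isna().mean() > max_missing:
            excluded.append(gene)
            continue
        per_group = [
            row[matrix.samples_in(g)].dropna().to_numpy() for g in groups
        ]
        if any(len(g) < 2 for g in per_group):
            excluded.append(gene)
            continue
        calibrator = float(row[control_samples].dropna().mean())
        case_mean = float(row[case_samples].dropna().mean())
        rq = relative_quantity(case_mean, calibrator)
        try:
            _, p = anova_oneway(per_group)
        except ValueError:
            excluded.append(gene)
            continue
        direction = call_differential(rq, p, fc_threshold=fc_threshold, alpha=alpha)
        calls.append(ExpressionCall(gene=gene, rq=rq, p_value=p, direction=direction))

    metadata = {
        "control_group": control_group,
        "case_group": case_group,
        "reference_genes": sorted(matrix.reference_genes),
        "reference_aggregation": "arithmetic mean on the Ct scale",
        "calibrator": "mean control-group dCt",
        "anova_scale": "dCt",
        "fc_threshold": fc_threshold,
        "alpha": alpha,
        "max_missing": max_missing,
    }
    return DdctResult(calls=calls, excluded=excluded, metadata=metadata)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_ct_matrix(
    values_path: str | Path, annotations_path: str | Path
) -> CtMatrix:
    """Load a Ct matrix.

    ``values_path``: CSV, first column gene labels, remaining columns
    samples; empty cells or the token ``Undetermined`` are missing.
    ``annotations_path``: TSV with columns sample, group; rows of the form
    ``#reference<TAB><gene>`` flag reference genes.
    """
    df = pd.read_csv(values_path, index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    sample_groups: dict[str, str] = {}
    reference_genes: set[str] = set()
    with open(annotations_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "#reference":
                reference_genes.add(parts[1].strip())
                continue
            if line.startswith("#") or parts[0].strip().lower() == "sample":
                continue
            sample_groups[parts[0].strip()] = parts[1].strip()
    return CtMatrix(
        values=df,
        sample_groups=sample_groups,
        reference_genes=frozenset(reference_genes),
    )


def write_ct_matrix(matrix: CtMatrix, values_path: str | Path,
                    annotations_path: str | Path) -> None:
    matrix.values.to_csv(values_path)
    with open(annotations_path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample in matrix.values.columns:
            fh.write(f"{sample}\t{matrix.sample_groups[sample]}\n")
        for gene in sorted(matrix.reference_genes):
            fh.write(f"#reference\t{gene}\n")
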
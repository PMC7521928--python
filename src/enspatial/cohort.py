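"""Replicate-level counting statistics.

Proportions of phenotypes per biological replicate (one fish, processed
independently), group summaries as mean ± sample SD, two-sided Mann-Whitney
comparisons between groups, Benjamini–Hochberg correction across the
comparison family, and the graded significance labels used in figures.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .frames import ImageFrame

__all__ = [
    "ReplicateProportion",
    "replicate_proportions",
    "summarize_proportions",
    "mann_whitney",
    "bh_adjust",
    "grade",
    "compare_groups",
]

#: Exact Mann-Whitney enumeration is used up to this combined sample size
#: when there are no ties; beyond it (or with ties) the tie-corrected normal
#: approximation applies.
EXACT_MAX_N = 20


@dataclass(frozen=True)
class ReplicateProportion:
    """Numerator/denominator cell-count ratio for one fish."""

    replicate: str
    group: str
    numerator: int
    denominator: int

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator


def replicate_proportions(
    frames: list[ImageFrame],
    numerator_phenotypes: tuple[str, ...] | str,
    denominator_phenotypes: tuple[str, ...] | str | None = None,
) -> list[ReplicateProportion]:
    """Per-replicate phenotype proportions from frames grouped by fish.

    ``denominator_phenotypes=None`` means all cells.  A replicate with a
    zero denominator is reported as missing with a warning and excluded.
    """
    if isinstance(numerator_phenotypes, str):
        numerator_phenotypes = (numerator_phenotypes,)
    if isinstance(denominator_phenotypes, str):
        denominator_phenotypes = (denominator_phenotypes,)

    by_fish: dict[tuple[str, str], list[ImageFrame]] = {}
    for f in frames:
        by_fish.setdefault((f.fish_id, f.group), []).append(f)

    out = []
    for (fish, group), fish_frames in by_fish.items():
        num = den = 0
        for f in fish_frames:
            counts = f.phenotype_counts()
            num += sum(counts.get(ph, 0) for ph in numerator_phenotypes)
            if denominator_phenotypes is None:
                den += f.n_cells
            else:
                den += sum(counts.get(ph, 0) for ph in denominator_phenotypes)
        if num > den:
            raise ValueError(
                f"replicate {fish!r}: numerator {num} exceeds denominator {den}; "
                "numerator phenotypes must be a subset of the denominator"
            )
        if den == 0:
            warnings.warn(
                f"replicate {fish!r} in group {group!r} has a zero denominator "
                "and is excluded from summaries",
                stacklevel=2,
            )
            continue
        out.append(ReplicateProportion(fish, group, num, den))
    return out


def summarize_proportions(props: list[ReplicateProportion]) -> pd.DataFrame:
    """Group mean ± sample SD of per-replicate proportions."""
    df = pd.DataFrame(
        {"group": p.group, "replicate": p.replicate, "proportion": p.proportion}
        for p in props
    )
    return (
        df.groupby("group", sort=False)["proportion"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first group, p).

    Exact enumeration when the combined sample is small (≤ 20) and tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain at least one value")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def grade(p: float) -> str:
    """Graded significance label: ns / * / ** / *** (boundaries inclusive)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    return "***"


def compare_groups(values_by_group: dict[str, list[float]]) -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons with BH correction and grades.

    The BH family is exactly the set of pairwise comparisons in this call;
    callers deciding on a different family should adjust over it explicitly.
    """
    pairs = list(itertools.combinations(values_by_group, 2))
    rows = []
    for ga, gb in pairs:
        u, p = mann_whitney(values_by_group[ga], values_by_group[gb])
        rows.append({"group_a": ga, "group_b": gb, "U": u, "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
        df["grade"] = [grade(p) for p in df["p_adjusted"]]
    return df
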
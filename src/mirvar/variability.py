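"""Intra-group expression-variability screening and cluster co-variation.

For each miRNA and group the screen computes the maximal-to-minimal ratio
(MAX/MIN) of the normalized replicate expressions and the coefficient of
variation (CV, sample standard deviation over mean). Hypervariable miRNAs
are those whose MAX/MIN exceeds mean + 2*STD of the MAX/MIN distribution in
a reference group; cluster co-variation is quantified as the mean pairwise
Pearson correlation of members' relative-expression vectors (a statistic
defined by this package — the underlying studies demonstrate co-variation
graphically).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .normalize import CountMatrix

__all__ = [
    "maxmin",
    "cv",
    "VariabilityTable",
    "variability_table",
    "hypervariability_screen",
    "relative_expression",
    "covariation_score",
]


class VariabilityDomainError(ValueError):
    pass


def maxmin(values: Sequence[float]) -> float:
    """max/min of non-negative replicate expressions.

    Returns ``inf`` when the minimum is zero (such rows are normally
    removed by the expression filter beforehand); all-zero input raises.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise VariabilityDomainError("expressions must be non-negative")
    if not (v > 0).any():
        raise VariabilityDomainError("MAX/MIN undefined for an all-zero row")
    lo = v.min()
    return math.inf if lo == 0 else float(v.max() / lo)


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample (n-1) standard deviation / mean."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m <= 0:
        raise VariabilityDomainError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / m)


@dataclass
class VariabilityTable:
    """Per-(miRNA, group) statistics plus per-group summaries.

    ``stats`` has a row per miRNA and a ('MAX/MIN'|'CV', group) column
    pair; rows are the group's expressed set (NaN elsewhere). ``summary``
    has one column per group with the fields of the classic profile table:
    number of expressed miRNAs, mean/STD of MAX/MIN, mean + 2 STD, count
    and percentage flagged hypervariable, mean/STD of CV.
    """

    stats: pd.DataFrame
    summary: pd.DataFrame
    threshold: float | None = None
    reference_group: str | None = None
    flags: pd.DataFrame | None = None


def variability_table(
    matrix: CountMatrix, expressed: dict[str, pd.Index]
) -> VariabilityTable:
    """MAX/MIN and CV for every expressed miRNA in every group."""
    norm = matrix.require_normalized()
    groups = matrix.group_names
    cols = pd.MultiIndex.from_product([["MAX/MIN", "CV"], groups])
    stats = pd.DataFrame(np.nan, index=norm.index, columns=cols)
    for g in groups:
        libs = matrix.libraries_of(g)
        sub = norm.loc[expressed[g], libs]
        lo = sub.min(axis=1)
        ratio = sub.max(axis=1) / lo.where(lo > 0)
        ratio = ratio.fillna(np.inf)
        stats.loc[expressed[g], ("MAX/MIN", g)] = ratio
        stats.loc[expressed[g], ("CV", g)] = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    summary = pd.DataFrame(index=_SUMMARY_ROWS, columns=groups, dtype=float)
    for g in groups:
        mm = stats[("MAX/MIN", g)].dropna()
        mm = mm[np.isfinite(mm)]
        c = stats[("CV", g)].dropna()
        summary.loc["n_expressed", g] = len(expressed[g])
        summary.loc["maxmin_mean", g] = mm.mean()
        summary.loc["maxmin_std", g] = mm.std(ddof=1)
        summary.loc["maxmin_mean_plus_2std", g] = mm.mean() + 2 * mm.std(ddof=1)
        summary.loc["cv_mean", g] = c.mean()
        summary.loc["cv_std", g] = c.std(ddof=1)
    return VariabilityTable(stats=stats, summary=summary)


_SUMMARY_ROWS = [
    "n_expressed",
    "maxmin_mean",
    "maxmin_std",
    "maxmin_mean_plus_2std",
    "n_hypervariable",
    "pct_hypervariable",
    "cv_mean",
    "cv_std",
]


def hypervariability_threshold(mean: float, std: float) -> float:
    """The screen's cut-off: mean + 2*STD of the reference MAX/MIN values."""
    return mean + 2.0 * std


def hypervariable_percentage(n_flagged: int, n_expressed: int) -> float:
    """Percentage of a group's expressed miRNAs flagged, to one decimal."""
    return round(100.0 * n_flagged / n_expressed, 1)


def hypervariability_screen(
    table: VariabilityTable,
    reference_group: str,
    per_group_thresholds: bool = False,
) -> VariabilityTable:
    """Flag hypervariable miRNAs.

    A single threshold — mean + 2*STD of MAX/MIN in ``reference_group`` —
    is applied to every group (strict ``>``); ``per_group_thresholds``
    instead screens each group against its own mean + 2*STD. Flags are
    monotone in MAX/MIN: raising a flagged miRNA's maximum never unflags
    it. Infinite MAX/MIN (a zero replicate) always flags.
    """
    if reference_group not in table.summary.columns:
        raise VariabilityDomainError(f"reference group {reference_group!r} absent")
    thr_ref = hypervariability_threshold(
        table.summary.loc["maxmin_mean", reference_group],
        table.summary.loc["maxmin_std", reference_group],
    )
    groups = list(table.summary.columns)
    flags = pd.DataFrame(False, index=table.stats.index, columns=groups)
    for g in groups:
        thr = (
            table.summary.loc["maxmin_mean_plus_2std", g]
            if per_group_thresholds
            else thr_ref
        )
        mm = table.stats[("MAX/MIN", g)]
        flags[g] = mm.notna() & (mm > thr)
        n = int(table.summary.loc["n_expressed", g])
        table.summary.loc["n_hypervariable", g] = flags[g].sum()
        table.summary.loc["pct_hypervariable", g] = hypervariable_percentage(
            int(flags[g].sum()), n
        )
    table.threshold = float(thr_ref)
    table.reference_group = reference_group
    table.flags = flags
    return table


def relative_expression(
    matrix: CountMatrix, mirna: str, group: str
) -> pd.Series:
    """Each replicate's normalized expression divided by the group mean
    (the output averages to 1)."""
    norm = matrix.require_normalized()
    libs = matrix.libraries_of(group)
    v = norm.loc[mirna, libs]
    m = v.mean()
    if m <= 0:
        raise VariabilityDomainError(f"{mirna}: zero mean in group {group}")
    return v / m


def covariation_score(
    matrix: CountMatrix, mirnas: Iterable[str], group: str
) -> tuple[float, int]:
    """Mean pairwise Pearson correlation of relative-expression vectors.

    Returns ``(score, n_pairs_used)``; pairs in which either member has
    zero variance across the replicates are skipped and not counted.
    """
    names = list(mirnas)
    if len(names) < 2:
        raise VariabilityDomainError("need at least two miRNAs")
    rel = {n: relative_expression(matrix, n, group).to_numpy() for n in names}
    rs = []
    for a, b in itertools.combinations(names, 2):
        if rel[a].std() == 0 or rel[b].std() == 0:
            continue
        rs.append(np.corrcoef(rel[a], rel[b])[0, 1])
    if not rs:
        raise VariabilityDomainError("all pairs degenerate (zero variance)")
    return float(np.mean(rs)), len(rs)
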
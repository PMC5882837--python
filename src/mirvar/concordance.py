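"""Partner-strand and cluster-level validation of differential-expression
calls, and the repeated-impact subset.

The -5p and -3p strands maturating from one hairpin duplex are expected to
change expression in parallel, so the fold-change of a significant miRNA
can be validated against its partner strand; miRNAs from one miR gene
cluster, potentially transcribed as a single RNA unit, are likewise
expected to move in the same direction. Combining partner confirmation
across two comparisons that share a reference group yields the subset of
miRNAs repeatedly impacted by the condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MiRNAReference, ReferenceError

__all__ = [
    "pair_partners",
    "r_squared",
    "confirm_by_partner",
    "cotranscription_check",
    "repeated_impact",
    "PartnerPairTable",
    "RepeatedImpactSet",
]


@dataclass
class PartnerPairTable:
    """Tier-1 miRNAs paired with their expressed partner strands.

    ``pairs`` columns: miRNA, FCE, padj, partner, partner_FCE,
    partner_padj, hairpin_id. ``partnerless`` lists tier-1 miRNAs whose
    partner strand is absent or not expressed (blank-cell rows).
    """

    pairs: pd.DataFrame
    partnerless: list[str] = field(default_factory=list)

    @property
    def r2(self) -> float:
        """R^2 of partner FCE against miRNA FCE over the table rows."""
        return r_squared(self.pairs["FCE"], self.pairs["partner_FCE"])


@dataclass
class RepeatedImpactSet:
    """miRNAs significant, with partner confirmation, in two comparisons
    against a common reference group."""

    members: list[str]
    fces: pd.DataFrame  # member x [comparison-1 FCE, comparison-2 FCE]
    cross_r2: float
    dropped: list[str] = field(default_factory=list)


def pair_partners(de: pd.DataFrame, reference: MiRNAReference) -> PartnerPairTable:
    """One row per tier-1 miRNA whose partner strand is in the tested set.

    The partner's FCE and padj come from the same comparison table; a
    tier-1 miRNA whose hairpin emits a single strand, or whose partner did
    not pass the expression filter, is listed as partnerless.
    """
    rows = []
    partnerless = []
    for name in de.index[de["tier"] == 1]:
        hp = reference.hairpin_of(name)  # raises ReferenceError if unknown
        partner = reference.partner_of(name)
        if partner is None or partner not in de.index:
            partnerless.append(name)
            continue
        rows.append(
            {
                "miRNA": name,
                "FCE": de.loc[name, "FCE"],
                "padj": de.loc[name, "padj"],
                "partner": partner,
                "partner_FCE": de.loc[partner, "FCE"],
                "partner_padj": de.loc[partner, "padj"],
                "hairpin_id": hp.hairpin_id,
            }
        )
    pairs = pd.DataFrame(
        rows,
        columns=[
            "miRNA",
            "FCE",
            "padj",
            "partner",
            "partner_FCE",
            "partner_padj",
            "hairpin_id",
        ],
    )
    return PartnerPairTable(pairs=pairs, partnerless=partnerless)


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Square of the Pearson correlation coefficient.

    Symmetric in (x, y) and invariant to affine rescaling of either
    argument; NaN (flagged undefined) when either input has zero variance
    or fewer than 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    r = stats.pearsonr(x, y)[0]
    return float(r * r)


def confirm_by_partner(
    pairs: PartnerPairTable, alpha_secondary: float = 5.0e-2
) -> pd.DataFrame:
    """Tier-1 miRNAs whose partner's padj is below the secondary threshold
    (strict ``<``), grouped by hairpin.

    Returns the confirmed subset of ``pairs.pairs`` — for these hairpins
    both strands stand as impacted.
    """
    sel = pairs.pairs["partner_padj"] < alpha_secondary
    return pairs.pairs[sel].reset_index(drop=True)


def cotranscription_check(
    de: pd.DataFrame, reference: MiRNAReference, alpha_primary: float = 1.0e-2
) -> pd.DataFrame:
    """Consistency report for clustered (potentially co-transcribed) miRNAs.

    For every pair of distinct-hairpin miRNAs from one miR gene cluster in
    which at least one member is tier-1, report both FCEs and padj values
    and whether the fold-changes lie on the same side of 1. Singleton
    clusters yield no rows.
    """
    rows = []
    for cluster_id, hairpin_ids in reference.clusters.items():
        if len(hairpin_ids) < 2:
            continue
        members = [m for m in reference.cluster_members(cluster_id) if m in de.index]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if reference.hairpin_of(a) is reference.hairpin_of(b):
                    continue  # partner strands are covered by pair_partners
                if not (de.loc[a, "tier"] == 1 or de.loc[b, "tier"] == 1):
                    continue
                fa, fb = de.loc[a, "FCE"], de.loc[b, "FCE"]
                rows.append(
                    {
                        "cluster_id": cluster_id,
                        "miRNA_a": a,
                        "FCE_a": fa,
                        "padj_a": de.loc[a, "padj"],
                        "miRNA_b": b,
                        "FCE_b": fb,
                        "padj_b": de.loc[b, "padj"],
                        "same_direction": bool((fa - 1.0) * (fb - 1.0) > 0),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "miRNA_a",
            "FCE_a",
            "padj_a",
            "miRNA_b",
            "FCE_b",
            "padj_b",
            "same_direction",
        ],
    )


def repeated_impact(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    confirmed: pd.DataFrame,
    reference: MiRNAReference | None = None,
    alpha_secondary: float = 5.0e-2,
    members_only_r2: bool = False,
) -> RepeatedImpactSet:
    """miRNAs impacted in both comparisons against the common reference.

    Candidates are both strands of every partner-confirmed hairpin from
    the first comparison, plus clustered strands of those hairpins that
    met the secondary threshold in the first comparison (the
    same-transcription-unit case). A candidate becomes a member iff its
    padj in the *second* comparison is also below ``alpha_secondary``;
    candidates failing there are reported as dropped.

    The cross-comparison R^2 is computed on the FCE pairs of all
    candidates present in both tables (``members_only_r2`` restricts it to
    the final members).
    """
    if de1.attrs.get("group_ref") != de2.attrs.get("group_ref"):
        raise ValueError("comparisons must share the reference group")
    candidates: list[str] = []
    for _, row in confirmed.iterrows():
        for name in (row["miRNA"], row["partner"]):
            if name not in candidates:
                candidates.append(name)
        if reference is not None:
            cluster = reference.cluster_of(row["miRNA"])
            for linked in reference.cluster_members(cluster):
                if (
                    linked not in candidates
                    and linked in de1.index
                    and de1.loc[linked, "padj"] < alpha_secondary
                ):
                    candidates.append(linked)
    members, dropped = [], []
    for name in candidates:
        if name in de2.index and de2.loc[name, "padj"] < alpha_secondary:
            members.append(name)
        else:
            dropped.append(name)
    r2_rows = members if members_only_r2 else [c for c in candidates if c in de2.index]
    fces = pd.DataFrame(
        {
            "FCE_1": de1.loc[r2_rows, "FCE"],
            "FCE_2": de2.loc[r2_rows, "FCE"],
        }
    )
    cross = r_squared(fces["FCE_1"], fces["FCE_2"]) if len(fces) >= 3 else math.nan
    return RepeatedImpactSet(
        members=members,
        fces=fces.loc[[m for m in members if m in fces.index]] if members_only_r2 else fces,
        cross_r2=cross,
        dropped=dropped,
    )
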
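"""Reference values from a published miRNome profiling study of the rat
hypothalamic arcuate nucleus (ARC) under perinatal and/or adult high-fat
diet challenge (four groups, C-C / C-HF / HF-C / HF-HF, six biological
replicates each).

These printed summary tables are bundled as inputs for cross-checks and
worked examples: the pipeline's arithmetic (hypervariability thresholds
and percentages, fold-change concordance R^2) can be recomputed from them
directly. The underlying sequencing data are not bundled; dataset-level
results are exercised on synthetic data instead.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "group_profile_summary",
    "partner_pairs_perinatal",
    "partner_pairs_combined",
    "repeated_impact_fces",
]


def group_profile_summary() -> pd.DataFrame:
    """Published per-group profile summary: number of expressed miRNAs
    (mean normalized expression >= 10), mean/STD of MAX/MIN, the printed
    mean + 2 STD, hypervariable counts at the reference threshold of 8.3,
    and mean/STD of CV."""
    data = {
        "C-C": [417, 2.6, 2.9, 8.3, 15, 3.6, 0.28, 0.18],
        "C-HF": [380, 3.5, 6.1, 15.7, 21, 5.5, 0.29, 0.16],
        "HF-C": [446, 3.2, 4.2, 11.6, 25, 5.6, 0.32, 0.20],
        "HF-HF": [440, 2.2, 1.6, 5.5, 6, 1.4, 0.24, 0.13],
    }
    return pd.DataFrame(
        data,
        index=[
            "n_expressed",
            "maxmin_mean",
            "maxmin_std",
            "maxmin_mean_plus_2std",
            "n_hypervariable",
            "pct_hypervariable",
            "cv_mean",
            "cv_std",
        ],
    )


_PAIRS_PERINATAL = [
    # miRNA, FCE, padj, partner, partner FCE, partner padj  (HF-C vs C-C)
    ("let-7i-5p", 1.9, 6.5e-03, "let-7i-3p", 1.5, 3.1e-01),
    ("miR-132-3p", 1.7, 5.1e-03, "miR-132-5p", 1.3, 2.5e-01),
    ("miR-140-5p", 1.7, 6.5e-03, "miR-140-3p", 0.9, 1.9e-01),
    ("miR-28-5p", 1.7, 6.9e-03, "miR-28-3p", 0.8, 9.3e-02),
    ("miR-221-5p", 1.9, 1.0e-02, "miR-221-3p", 1.6, 6.2e-02),
    ("miR-323-5p", 0.5, 6.5e-03, "miR-323-3p", 0.5, 1.1e-02),
    ("miR-338-5p", 1.5, 4.2e-03, "miR-338-3p", 1.4, 3.1e-01),
    ("miR-3585-5p", 4.8, 9.3e-03, "miR-3585-3p", 3.4, 3.1e-02),
    ("miR-433-3p", 0.6, 1.0e-02, "miR-433-5p", 0.6, 4.7e-02),
    ("miR-485-3p", 0.6, 1.8e-03, "miR-485-5p", 0.8, 4.2e-02),
    ("miR-543-3p", 0.8, 6.9e-03, "miR-543-5p", 0.6, 2.2e-02),
    ("miR-708-5p", 1.6, 7.7e-04, "miR-708-3p", 0.9, 3.4e-01),
    ("miR-770-3p", 0.6, 1.0e-02, "miR-770-5p", 0.6, 1.2e-02),
]

#: tier-1 miRNAs of the perinatal-only comparison without an expressed partner
PARTNERLESS_PERINATAL = [
    "miR-107-3p",
    "miR-1188-5p",
    "miR-668",
    "miR-673-5p",
    "miR-92a-3p",
]

_PAIRS_COMBINED = [
    # miRNA, FCE, padj, partner, partner FCE, partner padj  (HF-HF vs C-C,
    # the 34 pairs specific to the combined perinatal+adult challenge)
    ("let-7a-1-3p", 1.9, 4.0e-03, "let-7a-5p", 0.7, 6.5e-02),
    ("let-7i-5p", 1.6, 6.4e-03, "let-7i-3p", 1.4, 5.6e-02),
    ("miR-127-3p", 0.7, 9.2e-03, "miR-127-5p", 0.7, 2.3e-02),
    ("miR-132-3p", 1.9, 6.6e-03, "miR-132-5p", 1.1, 2.8e-01),
    ("miR-134-3p", 1.8, 8.1e-03, "miR-134-5p", 0.9, 6.3e-02),
    ("miR-139-3p", 0.6, 5.7e-03, "miR-139-5p", 0.7, 2.3e-02),
    ("miR-140-5p", 2.1, 3.0e-04, "miR-140-3p", 1.1, 3.3e-02),
    ("miR-145-5p", 3.4, 8.1e-03, "miR-145-3p", 2.1, 1.8e-02),
    ("miR-153-3p", 1.9, 9.7e-03, "miR-153-5p", 1.2, 1.8e-01),
    ("miR-154-5p", 1.5, 4.9e-03, "miR-154-3p", 0.8, 6.5e-02),
    ("miR-212-3p", 1.9, 3.1e-03, "miR-212-5p", 1.3, 5.1e-02),
    ("miR-23a-3p", 2.0, 3.0e-03, "miR-23a-5p", 0.8, 2.1e-01),
    ("miR-25-3p", 1.6, 5.7e-03, "miR-25-5p", 0.7, 1.5e-02),
    ("miR-27a-3p", 2.1, 1.0e-02, "miR-27a-5p", 2.6, 2.7e-02),
    ("miR-27b-3p", 1.8, 5.7e-03, "miR-27b-5p", 1.4, 8.1e-02),
    ("miR-28-5p", 1.7, 5.1e-03, "miR-28-3p", 0.9, 3.3e-01),
    ("miR-298-3p", 0.4, 2.0e-02, "miR-298-5p", 1.1, 2.7e-01),
    ("miR-29a-3p", 1.6, 9.7e-03, "miR-29a-5p", 1.7, 2.1e-02),
    ("miR-3068-5p", 1.8, 8.1e-04, "miR-3068-3p", 1.0, 4.8e-01),
    ("miR-329-3p", 0.7, 9.7e-03, "miR-329-5p", 1.0, 4.8e-01),
    ("miR-344b-1-3p", 0.5, 9.7e-03, "miR-344b-5p", 0.7, 2.1e-02),
    ("miR-34c-5p", 1.9, 2.9e-03, "miR-34c-3p", 1.2, 2.2e-01),
    ("miR-369-5p", 0.8, 5.3e-03, "miR-369-3p", 0.7, 4.4e-02),
    ("miR-376b-3p", 0.6, 9.7e-03, "miR-376b-5p", 1.0, 4.4e-01),
    ("miR-409a-5p", 0.6, 9.9e-03, "miR-409a-3p", 0.7, 2.5e-02),
    ("miR-434-3p", 0.7, 9.7e-03, "miR-434-5p", 1.3, 5.9e-02),
    ("miR-493-5p", 0.6, 9.7e-03, "miR-493-3p", 1.8, 1.7e-02),
    ("miR-505-5p", 0.7, 1.0e-02, "miR-505-3p", 1.2, 4.0e-02),
    ("miR-539-3p", 2.2, 7.7e-03, "miR-539-5p", 0.9, 1.5e-01),
    ("miR-652-5p", 1.9, 7.8e-03, "miR-652-3p", 1.1, 2.6e-01),
    ("miR-708-5p", 1.6, 3.6e-04, "miR-708-3p", 0.9, 3.1e-01),
    ("miR-7a-1-3p", 1.7, 8.1e-03, "miR-7a-5p", 1.2, 2.0e-01),
    ("miR-7a-2-3p", 1.7, 1.0e-02, "miR-7a-5p", 1.2, 2.0e-01),
    ("miR-872-5p", 1.6, 9.7e-03, "miR-872-3p", 1.1, 2.7e-01),
]

_REPEATED = [
    # miRNA, FCE and padj vs the control group in the perinatal-only
    # (HF-C) and combined (HF-HF) comparisons
    ("miR-323-3p", 0.5, 1.1e-02, 0.4, 5.3e-03),
    ("miR-323-5p", 0.5, 6.5e-03, 0.7, 5.3e-03),
    ("miR-3585-3p", 3.4, 3.1e-02, 3.2, 2.4e-02),
    ("miR-3585-5p", 4.8, 9.3e-03, 4.6, 2.3e-02),
    ("miR-433-3p", 0.6, 1.0e-02, 0.6, 2.0e-03),
    ("miR-433-5p", 0.6, 4.7e-02, 0.5, 1.7e-02),
    ("miR-485-3p", 0.6, 1.8e-03, 0.5, 5.1e-04),
    ("miR-485-5p", 0.8, 4.2e-02, 0.8, 2.2e-02),
    ("miR-543-3p", 0.8, 6.9e-03, 0.5, 1.7e-05),
    ("miR-543-5p", 0.6, 2.2e-02, 1.0, 4.2e-01),
    ("miR-547-3p", 3.3, 5.0e-02, 3.6, 5.2e-02),
    ("miR-770-3p", 0.6, 1.0e-02, 0.5, 5.3e-03),
    ("miR-770-5p", 0.6, 1.2e-02, 0.7, 1.1e-02),
]

_PAIR_COLS = ["miRNA", "FCE", "padj", "partner", "partner_FCE", "partner_padj"]


def partner_pairs_perinatal() -> pd.DataFrame:
    """The 13 published miRNA/partner fold-change pairs of the
    perinatal-only comparison (HF-C vs C-C) — the concordant set."""
    return pd.DataFrame(_PAIRS_PERINATAL, columns=_PAIR_COLS)


def partner_pairs_combined() -> pd.DataFrame:
    """The 34 published miRNA/partner pairs specific to the combined
    perinatal+adult comparison (HF-HF vs C-C) — the discordant set."""
    return pd.DataFrame(_PAIRS_COMBINED, columns=_PAIR_COLS)


def repeated_impact_fces() -> pd.DataFrame:
    """Published fold-changes/padj of the 13 perinatally impacted strands
    in both comparisons against the control group."""
    return pd.DataFrame(
        _REPEATED, columns=["miRNA", "FCE_1", "padj_1", "FCE_2", "padj_2"]
    )
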
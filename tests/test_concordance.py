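"""Partner-strand pairing, R^2 concordance, co-transcription consistency
and the repeated-impact subset."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirvar import concordance as conc
from mirvar import datasets
from mirvar.simulate import Hairpin, MiRNAReference, ReferenceError


def _reference():
    return MiRNAReference(
        [
            Hairpin("hp1", "clA", "m1-5p", "m1-3p", "A" * 20, "C" * 20),
            Hairpin("hp2", "clA", "m2-5p", "m2-3p", "G" * 20, "T" * 20),
            Hairpin("hp3", "cl3", "m3-5p", None, "AC" * 10, None),
            Hairpin("hp4", "cl4", "m4-5p", "m4-3p", "AG" * 10, "CT" * 10),
        ]
    )


def _de(rows, ref_group="C-C", trt="HF-C"):
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["FCE", "p", "padj", "tier"]
    ).astype(float)
    table["tier"] = table["tier"].astype(int)
    table.attrs.update(group_ref=ref_group, group_trt=trt, m=len(rows))
    return table


@pytest.fixture
def de1():
    return _de(
        {
            "m1-5p": (0.5, 1e-4, 1e-3, 1),  # tier-1, partner confirmed
            "m1-3p": (0.55, 1e-3, 1e-2, 1),
            "m2-5p": (1.8, 2e-3, 8e-3, 1),  # tier-1, partner NOT confirmed
            "m2-3p": (1.1, 0.4, 0.6, 0),
            "m3-5p": (2.2, 1e-3, 9e-3, 1),  # tier-1, no partner strand
            "m4-5p": (1.0, 0.9, 0.95, 0),
            "m4-3p": (1.0, 0.8, 0.9, 0),
        }
    )


@pytest.fixture
def de2():
    return _de(
        {
            "m1-5p": (0.45, 1e-4, 1e-3, 1),
            "m1-3p": (0.6, 2e-3, 2e-2, 2),
            "m2-5p": (1.6, 0.2, 0.4, 0),
            "m2-3p": (1.0, 0.9, 0.95, 0),
            "m3-5p": (2.0, 0.03, 0.06, 0),
            "m4-5p": (1.1, 0.5, 0.7, 0),
            "m4-3p": (0.9, 0.6, 0.8, 0),
        },
        trt="HF-HF",
    )


class TestPairPartners:
    def test_rows_and_partnerless_split(self, de1):
        table = conc.pair_partners(de1, _reference())
        assert set(table.pairs["miRNA"]) == {"m1-5p", "m1-3p", "m2-5p"}
        assert table.partnerless == ["m3-5p"]

    def test_single_strand_hairpin_never_paired(self, de1):
        table = conc.pair_partners(de1, _reference())
        assert "m3-5p" not in set(table.pairs["miRNA"])

    def test_unknown_mirna_rejected(self):
        bad = _de({"nope-5p": (1.5, 1e-3, 1e-3, 1)})
        with pytest.raises(ReferenceError):
            conc.pair_partners(bad, _reference())


class TestRSquared:
    def test_published_cross_comparison_value(self):
        t = datasets.repeated_impact_fces()
        assert round(conc.r_squared(t["FCE_1"], t["FCE_2"]), 2) == 0.98

    def test_perfect_affine_relation(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert conc.r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_hand_pearson_computation(self):
        assert conc.r_squared([1, 2, 3], [1, 3, 2]) == pytest.approx(0.25)

    def test_zero_variance_flagged_nan(self):
        assert math.isnan(conc.r_squared([1, 1, 1], [1, 2, 3]))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 100),
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_symmetry_and_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r2 = conc.r_squared(x, y)
        assert r2 == pytest.approx(conc.r_squared(y, x))
        assert r2 == pytest.approx(conc.r_squared(a * x + b, y), rel=1e-9)


class TestConfirmByPartner:
    def test_only_partner_significant_pairs_survive(self, de1):
        pairs = conc.pair_partners(de1, _reference())
        confirmed = conc.confirm_by_partner(pairs)
        assert set(confirmed["miRNA"]) == {"m1-5p", "m1-3p"}

    def test_boundary_is_strict(self, de1):
        pairs = conc.pair_partners(de1, _reference())
        pairs.pairs.loc[pairs.pairs["miRNA"] == "m2-5p", "partner_padj"] = 5.0e-2
        confirmed = conc.confirm_by_partner(pairs, alpha_secondary=5.0e-2)
        assert "m2-5p" not in set(confirmed["miRNA"])

    def test_all_partners_null_give_empty_set(self, de1):
        pairs = conc.pair_partners(de1, _reference())
        pairs.pairs["partner_padj"] = 1.0
        assert conc.confirm_by_partner(pairs).empty

    def test_output_subset_of_tier1(self, de1):
        pairs = conc.pair_partners(de1, _reference())
        confirmed = conc.confirm_by_partner(pairs)
        tier1 = set(de1.index[de1["tier"] == 1])
        assert set(confirmed["miRNA"]) <= tier1


class TestCotranscription:
    def test_clustered_tier1_pairs_reported_with_direction(self, de1):
        report = conc.cotranscription_check(de1, _reference())
        # hp1 and hp2 share cluster clA; four cross-hairpin strand pairs
        assert len(report) == 4
        m15_m25 = report[(report["miRNA_a"] == "m1-5p") & (report["miRNA_b"] == "m2-5p")]
        assert not bool(m15_m25["same_direction"].iloc[0])  # 0.5 vs 1.8

    def test_singleton_cluster_yields_no_rows(self, de1):
        only = _de({"m3-5p": (2.2, 1e-3, 9e-3, 1)})
        assert conc.cotranscription_check(only, _reference()).empty

    def test_same_hairpin_pairs_excluded(self, de1):
        report = conc.cotranscription_check(de1, _reference())
        same = report[report["miRNA_a"].str[:2] == report["miRNA_b"].str[:2]]
        assert same.empty


class TestRepeatedImpact:
    def test_members_need_second_comparison_significance(self, de1, de2):
        pairs = conc.pair_partners(de1, _reference())
        confirmed = conc.confirm_by_partner(pairs)
        ri = conc.repeated_impact(de1, de2, confirmed, _reference())
        assert set(ri.members) == {"m1-5p", "m1-3p"}
        # m2-5p enters as a linked clA strand (de1 padj < 5e-2) but fails
        # the second comparison, mirroring the dropped-strand case
        assert ri.dropped == ["m2-5p"]

    def test_member_failing_second_comparison_dropped(self, de1, de2):
        de2.loc["m1-3p", "padj"] = 0.2  # loses significance in comparison 2
        pairs = conc.pair_partners(de1, _reference())
        confirmed = conc.confirm_by_partner(pairs)
        ri = conc.repeated_impact(de1, de2, confirmed, _reference())
        assert ri.members == ["m1-5p"]
        assert "m1-3p" in ri.dropped

    def test_no_second_comparison_hits_empty_set(self, de1, de2):
        de2["padj"] = 1.0
        pairs = conc.pair_partners(de1, _reference())
        confirmed = conc.confirm_by_partner(pairs)
        ri = conc.repeated_impact(de1, de2, confirmed, _reference())
        assert ri.members == []

    def test_mismatched_reference_group_rejected(self, de1, de2):
        de2.attrs["group_ref"] = "other"
        with pytest.raises(ValueError):
            conc.repeated_impact(de1, de2, conc.confirm_by_partner(conc.pair_partners(de1, _reference())), _reference())

    def test_members_subset_of_confirmed_union_partners(self, de1, de2):
        pairs = conc.pair_partners(de1, _reference())
        confirmed = conc.confirm_by_partner(pairs)
        ri = conc.repeated_impact(de1, de2, confirmed, _reference())
        allowed = set(confirmed["miRNA"]) | set(confirmed["partner"])
        # plus linked cluster strands meeting the secondary threshold in de1
        for m in set(confirmed["miRNA"]):
            allowed |= {
                x
                for x in _reference().cluster_members(_reference().cluster_of(m))
                if x in de1.index and de1.loc[x, "padj"] < 5e-2
            }
        assert set(ri.members) <= allowed


class TestPublishedPairTables:
    def test_concordant_set_high_r2_discordant_low(self):
        hi = datasets.partner_pairs_perinatal()
        lo = datasets.partner_pairs_combined()
        r2_hi = conc.r_squared(hi["FCE"], hi["partner_FCE"])
        r2_lo = conc.r_squared(lo["FCE"], lo["partner_FCE"])
        assert r2_hi > 0.85
        assert r2_lo < 0.2
        assert round(r2_lo, 2) == 0.15

    def test_six_of_thirteen_partners_confirmed(self):
        pairs = datasets.partner_pairs_perinatal()
        assert len(pairs) == 13
        assert int((pairs["partner_padj"] < 5.0e-2).sum()) == 6
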
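"""Exact two-group tests, dispersion estimation, BH adjustment and the
differential-expression table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirvar import differential as diff
from mirvar import normalize as norm
from mirvar.differential import (
    DEError,
    bh_adjust,
    de_table,
    fce,
    mannwhitney_exact,
    nbinom_exact_test,
)


def poisson_conditional_oracle(ka, kb, sa, sb):
    """Independent oracle for the dispersion->0 limit: conditionally on the
    total, a Poisson split is Binomial(total, mu_a/(mu_a+mu_b)); sum the
    binomial probabilities of outcomes no more likely than observed."""
    ka, kb = np.asarray(ka), np.asarray(kb)
    sa, sb = np.asarray(sa, float), np.asarray(sb, float)
    q0 = np.mean(np.concatenate([ka, kb]) / np.concatenate([sa, sb]))
    mu_a, mu_b = q0 * sa.sum(), q0 * sb.sum()
    total = int(ka.sum() + kb.sum())
    if total == 0:
        return 1.0
    pi = mu_a / (mu_a + mu_b)
    pmf = stats.binom.pmf(np.arange(total + 1), total, pi)
    p_obs = stats.binom.pmf(int(ka.sum()), total, pi)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


class TestMannWhitney:
    def test_identical_multisets_give_p_one(self):
        a = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        assert mannwhitney_exact(a, a) == 1.0

    def test_complete_separation_floor_6v6(self):
        p = mannwhitney_exact([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12])
        assert p == pytest.approx(2 / 924, abs=1e-15)

    def test_two_vs_two_enumeration(self):
        assert mannwhitney_exact([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(loc=0.8, size=6)
            expected = stats.mannwhitneyu(a, b, method="exact").pvalue
            assert mannwhitney_exact(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        a=st.lists(st.integers(0, 50), min_size=2, max_size=6),
        b=st.lists(st.integers(0, 50), min_size=2, max_size=6),
    )
    def test_symmetry_and_range(self, a, b):
        p = mannwhitney_exact(a, b)
        assert p == mannwhitney_exact(b, a)
        assert 0 < p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(DEError):
            mannwhitney_exact([], [1, 2])


class TestNBExact:
    def test_equal_sums_symmetric_model_p_one(self):
        s = [1.0] * 6
        p = nbinom_exact_test([10, 12, 8, 10, 9, 11], [9, 11, 10, 10, 12, 8], s, s, 0.05)
        assert p == 1.0

    def test_total_ten_vs_zero_matches_direct_enumeration(self):
        s = [1.0] * 3
        p = nbinom_exact_test([4, 3, 3], [0, 0, 0], s, s, 0.0)
        # Binomial(10, 1/2): only the two extreme splits are as unlikely
        expected = 2 * stats.binom.pmf(0, 10, 0.5)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_poisson_limit_matches_oracle_on_small_totals(self, rng):
        for _ in range(25):
            ka = rng.integers(0, 30, size=6)
            kb = rng.integers(0, 30, size=6)
            if ka.sum() + kb.sum() == 0:
                continue
            sa = rng.uniform(0.5, 2.0, size=6)
            sb = rng.uniform(0.5, 2.0, size=6)
            mine = nbinom_exact_test(ka, kb, sa, sb, 0.0)
            oracle = poisson_conditional_oracle(ka, kb, sa, sb)
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_windowed_summation_consistent_with_full(self):
        # same statistic far above the windowing cut-off vs a scaled copy
        ka = np.array([9000, 11000, 10000, 9500, 10500, 10000])
        kb = (ka * 1.4).astype(int)
        s = np.ones(6)
        p_big = nbinom_exact_test(ka, kb, s, s, 0.02)
        assert 0 < p_big < 1e-3  # strong effect, finite probability

    def test_non_integer_counts_rejected(self):
        with pytest.raises(DEError):
            nbinom_exact_test([1.5, 2.0], [1, 2], [1, 1], [1, 1], 0.1)

    def test_all_zero_counts_give_p_one(self):
        s = [1.0] * 4
        assert nbinom_exact_test([0] * 4, [0] * 4, s, s, 0.1) == 1.0


class TestBH:
    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.001, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.004, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.021])[0] == pytest.approx(0.021)

    def test_out_of_range_rejected(self):
        with pytest.raises(DEError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_order_invariance_monotonicity_and_dominance(self, pvals):
        adj = bh_adjust(pvals)
        perm = np.random.default_rng(0).permutation(len(pvals))
        adj_perm = bh_adjust(list(np.asarray(pvals)[perm]))
        assert np.allclose(adj[perm], adj_perm)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


def _normalized_matrix(values, groups):
    counts = pd.DataFrame(values).T
    counts.columns = groups.index
    cm = norm.CountMatrix(counts.astype(int), groups)
    cm.size_factors = pd.Series(1.0, index=counts.columns)
    cm.normalized = counts.astype(float)
    return cm


class TestFCEAndTable:
    @pytest.fixture
    def matrix(self):
        libs = [f"R_{i}" for i in range(6)] + [f"T_{i}" for i in range(6)]
        groups = pd.Series(["R"] * 6 + ["T"] * 6, index=libs)
        return _normalized_matrix(
            {
                "equal": [50] * 12,
                "double": [50] * 6 + [100] * 6,
                "dim": [100, 110, 90, 105, 95, 100, 48, 52, 50, 55, 45, 50],
            },
            groups,
        )

    def test_equal_group_means_give_unit_fce(self, matrix):
        assert fce(matrix, "equal", "R", "T") == 1.0

    def test_doubled_treatment_mean_gives_two(self, matrix):
        assert fce(matrix, "double", "R", "T") == 2.0

    def test_table_contains_fce_p_padj_tiers(self, matrix):
        table = de_table(matrix, "R", "T", test="mw")
        assert list(table.columns) == ["FCE", "p", "padj", "tier"]
        assert table.attrs["m"] == 3
        assert table.loc["dim", "FCE"] == pytest.approx(0.5, abs=0.01)
        assert (table["padj"] >= table["p"] - 1e-15).all()

    def test_single_mirna_padj_equals_p(self):
        libs = [f"R_{i}" for i in range(6)] + [f"T_{i}" for i in range(6)]
        groups = pd.Series(["R"] * 6 + ["T"] * 6, index=libs)
        cm = _normalized_matrix(
            {"only": [100, 110, 90, 105, 95, 100, 48, 52, 50, 55, 45, 50]}, groups
        )
        table = de_table(cm, "R", "T", test="mw")
        assert table["padj"].iloc[0] == table["p"].iloc[0]

    def test_identical_group_labels_rejected(self, matrix):
        with pytest.raises(DEError):
            de_table(matrix, "R", "R")

    def test_mw_floor_reached_on_separated_counts(self, matrix):
        table = de_table(matrix, "R", "T", test="mw")
        assert table.loc["dim", "p"] == pytest.approx(2 / 924)


class TestDispersion:
    def test_floor_applied_to_near_poisson_data(self, rng):
        libs = [f"A_{i}" for i in range(8)] + [f"B_{i}" for i in range(8)]
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=libs)
        counts = pd.DataFrame(
            rng.poisson(200.0, size=(40, 16)),
            index=[f"m{i}" for i in range(40)],
            columns=libs,
        )
        cm = norm.normalize(norm.CountMatrix(counts, groups))
        disp = diff.estimate_dispersions(cm, "A", "B")
        assert (disp >= diff.DISPERSION_FLOOR).all()

    def test_recovers_true_dispersion_scale(self, rng):
        # NB counts at alpha=0.1: conservative estimate should land within
        # a factor of a few of the truth, never below the floor
        alpha, mu = 0.1, 500.0
        n = 1 / alpha
        libs = [f"A_{i}" for i in range(6)] + [f"B_{i}" for i in range(6)]
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=libs)
        counts = pd.DataFrame(
            rng.negative_binomial(n, n / (n + mu), size=(300, 12)), columns=libs
        )
        cm = norm.normalize(norm.CountMatrix(counts, groups))
        disp = diff.estimate_dispersions(cm, "A", "B")
        assert 0.05 < disp.median() < 0.4
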
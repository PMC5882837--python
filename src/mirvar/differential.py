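"""Two-group differential expression per miRNA.

Two tests are shipped and clearly labelled in all outputs:

* ``mw`` — the exact two-sided Mann-Whitney rank-sum test, enumerating the
  full permutation distribution (mid-ranks for ties). With 6 vs 6
  replicates its smallest attainable two-sided p is 2/924, which makes it
  the natural choice for phenotype-style measurements but a blunt
  instrument for counts.
* ``nb`` (default) — an exact conditional negative-binomial test in the
  style of the classical DESeq procedure: the two group *sums* are
  modelled as NB variables whose means and variances derive from a pooled
  expression estimate, per-library size factors and a per-miRNA dispersion
  (method-of-moments with a fitted mean-dispersion trend, floored at
  1e-8); the p-value is the probability, conditional on the total, of
  outcomes at most as likely as the one observed.

Fold-change of expression (FCE) is the ratio of mean normalized expression
in the treatment group to that in the reference group; multiple testing is
controlled per comparison with Benjamini-Hochberg over the tested set.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .normalize import CountMatrix, tested_set

__all__ = [
    "mannwhitney_exact",
    "nbinom_exact_test",
    "estimate_dispersions",
    "bh_adjust",
    "fce",
    "de_table",
    "volcano_frame",
]

DISPERSION_FLOOR = 1e-8
#: relative tolerance when comparing outcome probabilities to the observed
#: one (guards against ties lost to floating-point rounding)
_PROB_TOL = 1e-7


class DEError(ValueError):
    pass


@lru_cache(maxsize=32)
def _rank_subsets(n: int, m: int) -> np.ndarray:
    """All C(n+m, n) index subsets of size n, as an array of index rows."""
    return np.array(list(combinations(range(n + m), n)), dtype=np.intp)


def mannwhitney_exact(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided Mann-Whitney p by full permutation enumeration.

    Mid-ranks are used for ties; the two-sided p is 2 x min(tail
    probability), capped at 1. Intended for the exact regime (n <= 10 per
    group). Symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DEError("both groups must be non-empty")
    if a.size > 10 or b.size > 10:
        raise DEError("exact enumeration is limited to n <= 10 per group")
    ranks = stats.rankdata(np.concatenate([a, b]))
    subsets = _rank_subsets(a.size, b.size)
    w_all = ranks[subsets].sum(axis=1)
    w_obs = ranks[: a.size].sum()
    n_tot = w_all.size
    eps = 1e-9
    lower = np.count_nonzero(w_all <= w_obs + eps) / n_tot
    upper = np.count_nonzero(w_all >= w_obs - eps) / n_tot
    return min(1.0, 2.0 * min(lower, upper))


def _group_sum_logpmf(total_grid: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log pmf of a group-sum count modelled as NB(mu, var) (Poisson when
    var == mu)."""
    if var <= mu * (1 + 1e-12):
        return stats.poisson.logpmf(total_grid, mu)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return stats.nbinom.logpmf(total_grid, r, p)


def nbinom_exact_test(
    a_counts: Sequence[int],
    b_counts: Sequence[int],
    size_factors_a: Sequence[float],
    size_factors_b: Sequence[float],
    dispersion: float,
) -> float:
    """Exact conditional test on raw counts of one miRNA.

    The group sums K_A and K_B are modelled as NB with mean ``q0 * sum(s_j)``
    and variance ``q0 * sum(s_j) + dispersion * q0^2 * sum(s_j^2)`` under a
    common expression level q0 (the pooled mean of normalized counts); the
    reported p is the total conditional probability, given K_A + K_B, of
    splits no more likely than the observed one. ``dispersion = 0`` is the
    Poisson limit (equivalently a binomial-conditioned test).
    """
    ka = np.asarray(a_counts)
    kb = np.asarray(b_counts)
    if not (np.issubdtype(ka.dtype, np.integer) and np.issubdtype(kb.dtype, np.integer)):
        raise DEError("the exact NB test operates on raw integer counts")
    if dispersion < 0:
        raise DEError("dispersion must be >= 0")
    sa = np.asarray(size_factors_a, dtype=float)
    sb = np.asarray(size_factors_b, dtype=float)
    s_all = np.concatenate([sa, sb])
    q0 = float(np.mean(np.concatenate([ka, kb]) / s_all))
    total = int(ka.sum() + kb.sum())
    if total == 0 or q0 == 0:
        return 1.0
    mu_a = q0 * sa.sum()
    mu_b = q0 * sb.sum()
    var_a = mu_a + dispersion * q0 * q0 * (sa * sa).sum()
    var_b = mu_b + dispersion * q0 * q0 * (sb * sb).sum()

    if total <= 50_000:
        grid = np.arange(total + 1)
    else:
        # the conditional distribution has negligible mass outside a wide
        # window around the two marginal means; 50 sd is vastly beyond any
        # representable tail mass
        half = 50.0 * math.sqrt(max(var_a, var_b))
        lo = max(0, int(min(mu_a - half, total - mu_b - half)))
        hi = min(total, int(max(mu_a + half, total - mu_b + half)) + 1)
        grid = np.arange(lo, hi + 1)
        if int(ka.sum()) not in grid:
            grid = np.union1d(grid, [int(ka.sum())])
    lp = _group_sum_logpmf(grid, mu_a, var_a) + _group_sum_logpmf(
        total - grid, mu_b, var_b
    )
    lp_obs = (
        _group_sum_logpmf(np.array([int(ka.sum())]), mu_a, var_a)
        + _group_sum_logpmf(np.array([int(kb.sum())]), mu_b, var_b)
    )[0]
    mask = lp <= lp_obs + math.log1p(_PROB_TOL)
    log_num = logsumexp(lp[mask])
    log_den = logsumexp(lp)
    return float(min(1.0, math.exp(log_num - log_den)))


def estimate_dispersions(
    matrix: CountMatrix, group_a: str, group_b: str, rows: pd.Index | None = None
) -> pd.Series:
    """Per-miRNA NB dispersion for a two-group comparison.

    Within each group a method-of-moments estimate
    ``(var - mean * E[1/s]) / mean^2`` is computed on normalized counts
    (within-group, so planted signal does not inflate it); the two are
    averaged, a parametric trend ``alpha(mu) = a0/mu + a1`` is fitted by
    non-negative least squares over miRNAs with positive raw estimates,
    and the final value is ``max(raw, trend, 1e-8)`` — deliberately
    conservative.
    """
    norm = matrix.require_normalized()
    s = matrix.size_factors
    if s is None:
        raise DEError("size factors required for dispersion estimation")
    if rows is None:
        rows = norm.index
    raws = []
    for g in (group_a, group_b):
        libs = matrix.libraries_of(g)
        sub = norm.loc[rows, libs]
        q = sub.mean(axis=1)
        w = sub.var(axis=1, ddof=1)
        xi = float((1.0 / s[libs]).mean())
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (w - q * xi) / (q * q)
        raws.append(raw.where(q > 0))
    raw = pd.concat(raws, axis=1).mean(axis=1)
    q0 = norm.loc[rows, matrix.libraries_of(group_a) + matrix.libraries_of(group_b)].mean(axis=1)
    ok = raw.notna() & (raw > 0) & (q0 > 0)
    if ok.sum() >= 2:
        design = np.column_stack([1.0 / q0[ok].to_numpy(), np.ones(int(ok.sum()))])
        coef, _ = optimize.nnls(design, raw[ok].to_numpy())
        trend = coef[0] / q0.where(q0 > 0) + coef[1]
    else:
        trend = pd.Series(0.0, index=rows)
    final = pd.concat(
        [raw.fillna(0.0), trend.fillna(0.0)], axis=1
    ).max(axis=1).clip(lower=DISPERSION_FLOOR)
    final.name = "dispersion"
    return final


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DEError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fce(
    matrix: CountMatrix,
    mirna: str,
    group_ref: str,
    group_trt: str,
    statistic: str = "mean",
) -> float:
    """Fold-change of expression: treatment-group over reference-group
    average normalized expression (``statistic='median'`` for medians).
    NaN when the reference average is zero."""
    norm = matrix.require_normalized()
    agg = {"mean": np.mean, "median": np.median}[statistic]
    ref = float(agg(norm.loc[mirna, matrix.libraries_of(group_ref)]))
    trt = float(agg(norm.loc[mirna, matrix.libraries_of(group_trt)]))
    if ref == 0:
        return math.nan
    return trt / ref


def de_table(
    matrix: CountMatrix,
    group_ref: str,
    group_trt: str,
    test: str = "nb",
    expression_threshold: float = 10.0,
    tested_rule: str = "union",
    alpha_primary: float = 1.0e-2,
    alpha_secondary: float = 5.0e-2,
    fce_statistic: str = "mean",
) -> pd.DataFrame:
    """Per-miRNA differential-expression table for one comparison.

    Rows are the tested set (by default the union of the two groups'
    expressed sets); columns are FCE, p, padj and the significance tier
    (1: padj < ``alpha_primary``; 2: padj < ``alpha_secondary``; 0
    otherwise). The tested-set size, test name and thresholds are stored
    in ``DataFrame.attrs``.
    """
    if group_ref == group_trt:
        raise DEError("reference and treatment groups must differ")
    norm = matrix.require_normalized()
    rows = tested_set(matrix, group_ref, group_trt, expression_threshold, tested_rule)
    libs_ref = matrix.libraries_of(group_ref)
    libs_trt = matrix.libraries_of(group_trt)
    ref_mean = norm.loc[rows, libs_ref].agg(fce_statistic, axis=1)
    trt_mean = norm.loc[rows, libs_trt].agg(fce_statistic, axis=1)
    fces = (trt_mean / ref_mean.where(ref_mean > 0)).to_numpy()

    if test == "mw":
        pvals = np.array(
            [
                mannwhitney_exact(norm.loc[r, libs_ref], norm.loc[r, libs_trt])
                for r in rows
            ]
        )
    elif test == "nb":
        disp = estimate_dispersions(matrix, group_ref, group_trt, rows)
        s = matrix.size_factors
        ka = matrix.counts.loc[rows, libs_ref].to_numpy()
        kb = matrix.counts.loc[rows, libs_trt].to_numpy()
        sa = s[libs_ref].to_numpy()
        sb = s[libs_trt].to_numpy()
        pvals = np.array(
            [
                nbinom_exact_test(ka[i], kb[i], sa, sb, float(disp.iloc[i]))
                for i in range(len(rows))
            ]
        )
    else:
        raise DEError(f"unknown test {test!r} (expected 'mw' or 'nb')")

    padj = bh_adjust(pvals)
    tier = np.where(padj < alpha_primary, 1, np.where(padj < alpha_secondary, 2, 0))
    out = pd.DataFrame(
        {"FCE": fces, "p": pvals, "padj": padj, "tier": tier}, index=rows
    )
    out.attrs.update(
        m=len(rows),
        test=test,
        group_ref=group_ref,
        group_trt=group_trt,
        alpha_primary=alpha_primary,
        alpha_secondary=alpha_secondary,
    )
    return out


def volcano_frame(de: pd.DataFrame) -> pd.DataFrame:
    """log2 FCE vs -log10 padj, the classic volcano-plot coordinates."""
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "log2_FCE": np.log2(de["FCE"]),
                "neg_log10_padj": -np.log10(de["padj"]),
            },
            index=de.index,
        )
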
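"""Count-matrix container, median-of-ratios normalization and the
mean-expression filter.

Size factors follow the classical DESeq procedure: for library j,

    s_j = median_i  k_ij / (prod_v k_iv)^(1/m)

over the rows i whose counts are positive in every library (rows with any
zero are excluded from the geometric-mean reference). The geometric mean of
the factors is not constrained to 1. Normalized values are raw counts
divided by the library's size factor.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizationError",
    "size_factors",
    "normalize",
    "expression_filter",
    "tested_set",
    "read_count_matrix",
    "write_count_matrix",
]


class NormalizationError(ValueError):
    pass


class CountMatrix:
    """Integer miRNA x library counts with group labels.

    ``counts`` rows are mature miRNA names, columns are library labels;
    ``groups`` maps each library to its experimental group. Size factors
    and normalized values are attached by :func:`normalize`.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        groups: pd.Series | Mapping[str, str],
        size_factors: pd.Series | None = None,
    ):
        counts = counts.copy()
        if (counts.to_numpy() < 0).any():
            raise NormalizationError("raw counts must be non-negative")
        groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
        groups = groups.reindex(counts.columns)
        if groups.isna().any():
            missing = list(groups[groups.isna()].index)
            raise NormalizationError(f"libraries without a group label: {missing}")
        self.counts = counts
        self.groups = groups
        self.size_factors = size_factors
        self.normalized: pd.DataFrame | None = None

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def libraries_of(self, group: str) -> list[str]:
        libs = list(self.groups[self.groups == group].index)
        if not libs:
            raise NormalizationError(f"unknown group label {group!r}")
        return libs

    def subset(self, groups: Iterable[str]) -> "CountMatrix":
        libs = [lib for g in groups for lib in self.libraries_of(g)]
        sub = CountMatrix(self.counts[libs], self.groups[libs])
        if self.size_factors is not None:
            sub.size_factors = self.size_factors[libs]
        if self.normalized is not None:
            sub.normalized = self.normalized[libs]
        return sub

    def require_normalized(self) -> pd.DataFrame:
        if self.normalized is None:
            raise NormalizationError("matrix has not been normalized")
        return self.normalized


def size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per library."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    k = counts.to_numpy(dtype=float)
    positive = (k > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no row with all-positive counts; size factors are undefined"
        )
    logs = np.log(k[positive])
    log_geo = logs.mean(axis=1)
    ratios = np.exp(logs - log_geo[:, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize(matrix: CountMatrix, scope: str = "global") -> CountMatrix:
    """Attach size factors and normalized values (raw / factor).

    ``scope='global'`` computes one set of factors over all libraries
    (used for between-group comparisons); ``scope='group'`` computes
    factors within each group separately (used for within-group
    variability screening).
    """
    if scope == "global":
        s = size_factors(matrix)
    elif scope == "group":
        parts = [size_factors(matrix.counts[matrix.libraries_of(g)]) for g in matrix.group_names]
        s = pd.concat(parts).reindex(matrix.counts.columns)
    else:
        raise NormalizationError(f"unknown normalization scope {scope!r}")
    if (s <= 0).any():
        raise NormalizationError("size factors must be positive")
    matrix.size_factors = s
    matrix.normalized = matrix.counts / s
    return matrix


def expression_filter(
    matrix: CountMatrix, group: str, threshold: float = 10.0
) -> pd.Index:
    """miRNAs whose *mean* normalized expression in ``group`` is >= threshold.

    The boundary is closed: a group mean of exactly ``threshold`` is kept.
    """
    norm = matrix.require_normalized()
    libs = matrix.libraries_of(group)
    means = norm[libs].mean(axis=1)
    return matrix.counts.index[means >= threshold]


def tested_set(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    threshold: float = 10.0,
    rule: str = "union",
) -> pd.Index:
    """The miRNAs entering a two-group comparison.

    Default is the union of the two groups' expressed sets (most inclusive);
    ``rule='intersection'`` restricts to miRNAs expressed in both.
    """
    a = expression_filter(matrix, group_a, threshold)
    b = expression_filter(matrix, group_b, threshold)
    if rule == "union":
        keep = a.union(b)
    elif rule == "intersection":
        keep = a.intersection(b)
    else:
        raise NormalizationError(f"unknown tested-set rule {rule!r}")
    # preserve matrix row order
    return matrix.counts.index[matrix.counts.index.isin(keep)]


# ---------------------------------------------------------------------------
# TSV with a two-line header (library labels, then group labels)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("miRNA\t" + "\t".join(matrix.counts.columns) + "\n")
        fh.write("group\t" + "\t".join(matrix.groups) + "\n")
        for name, row in matrix.counts.iterrows():
            fh.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_count_matrix(path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_line = fh.readline().rstrip("\n").split("\t")
        if header[0] != "miRNA" or group_line[0] != "group":
            raise NormalizationError(f"{path}: not a two-line-header count TSV")
        libs = header[1:]
        groups = pd.Series(group_line[1:], index=libs)
        body = pd.read_csv(fh, sep="\t", header=None, names=["miRNA"] + libs)
    counts = body.set_index("miRNA")
    return CountMatrix(counts.astype(np.int64), groups)
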
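"""Between- versus within-ecotype differentiation contrasts.

The headline comparison: for two ecotype groups (e.g. fish-eating
residents and mammal-eating transients), form every ratio
FST(between-ecotype population pair) / FST(within-ecotype population
pair) -- the full Cartesian product of between pairs and within pairs.
Neutral and outlier locus sets each yield such a ratio set; a
Mann-Whitney U test compares them, and 2x2 contingency tables of summed
allelic differences (Yates-corrected chi-square) contrast the
fold-change between and within ecotypes, or against outgroup
populations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .popgen_stats import PairwiseLayer


@dataclass
class RatioContrast:
    group_a: list[str]
    group_b: list[str]
    between_pairs: list[tuple[str, str]]
    within_pairs: list[tuple[str, str]]
    ratios: np.ndarray
    label: str = ""

    @property
    def n(self) -> int:
        return len(self.ratios)

    @property
    def mean(self) -> float:
        return float(self.ratios.mean())

    @property
    def min(self) -> float:
        return float(self.ratios.min())

    @property
    def max(self) -> float:
        return float(self.ratios.max())


@dataclass
class RankTestResult:
    u: float
    z: float
    p: float
    method: str  # "exact" or "normal"


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2x2 integer counts, rows = (neutral, outlier)
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    fold_ratios: tuple[float, float]
    chi2: float
    p: float
    dof: int = 1


def ratio_set(
    layer: PairwiseLayer,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> RatioContrast:
    """All between-group / within-group FST ratios for two ecotype groups."""
    group_a, group_b = list(group_a), list(group_b)
    between = [(a, b) for a in group_a for b in group_b]
    within = list(itertools.combinations(group_a, 2)) + list(itertools.combinations(group_b, 2))
    if not within:
        raise ValueError("no within-ecotype population pair exists; ratio undefined")
    if not between:
        raise ValueError("no between-ecotype population pair exists")
    ratios = np.array(
        [layer.get(*bp) / layer.get(*wp) for bp in between for wp in within]
    )
    return RatioContrast(
        group_a=group_a,
        group_b=group_b,
        between_pairs=between,
        within_pairs=within,
        ratios=ratios,
        label=layer.label,
    )


def _exact_u_sf(m: int, n: int) -> np.ndarray:
    """Number of arrangements achieving each U value (no ties), U in 0..m*n.

    Coefficients of the Gaussian-binomial generating function
    prod_{j=1}^{m} (1 - x^{n+j}) / (1 - x^{j}).
    """
    poly = np.zeros(m * n + 1)
    poly[0] = 1.0
    for j in range(1, m + 1):
        # multiply by (1 + x^1 + ... ) truncated convolution with 1/(1-x^j)
        for u in range(j, m * n + 1):
            poly[u] += poly[u - j]
        for u in range(m * n, n + j - 1, -1):
            poly[u] -= poly[u - (n + j)]
    return poly


def mann_whitney(set1: Sequence[float], set2: Sequence[float]) -> RankTestResult:
    """Mann-Whitney U with midrank ties, tie-corrected variance and
    continuity correction; exact enumeration when m*n <= 400 and no ties.

    The sign convention: Z is negative when ``set1`` is stochastically
    smaller than ``set2``.
    """
    x = np.asarray(set1, dtype=float)
    y = np.asarray(set2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both sets must be non-empty")
    m, n = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r1 = ranks[:m].sum()
    u1 = r1 - m * (m + 1) / 2.0

    N = m + n
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
    var = m * n / 12.0 * ((N + 1) - tie_term)
    if var == 0:
        return RankTestResult(u=float(u1), z=0.0, p=1.0, method="degenerate")

    cc = 0.5 if u1 < m * n / 2.0 else (-0.5 if u1 > m * n / 2.0 else 0.0)
    z = (u1 - m * n / 2.0 + cc) / np.sqrt(var)
    p_normal = float(2.0 * norm.sf(abs(z)))

    has_ties = (counts > 1).any()
    if m * n <= 400 and not has_ties:
        poly = _exact_u_sf(m, n)
        total = poly.sum()
        u_int = int(round(u1))
        lower = poly[: u_int + 1].sum() / total
        upper = poly[u_int:].sum() / total
        p = float(min(1.0, 2.0 * min(lower, upper)))
        return RankTestResult(u=float(u1), z=float(z), p=p, method="exact")
    return RankTestResult(u=float(u1), z=float(z), p=min(1.0, p_normal), method="normal")


def _sum_over_pairs(layer: PairwiseLayer, pairs: Sequence[tuple[str, str]]) -> float:
    return float(sum(layer.get(a, b) for a, b in pairs))


def _yates_result(
    cell_neutral: tuple[float, float],
    cell_outlier: tuple[float, float],
    col_labels: tuple[str, str],
) -> ContingencyResult:
    from scipy.stats import chi2_contingency

    table = np.rint(np.array([cell_neutral, cell_outlier])).astype(np.int64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"contingency table has a zero marginal: {table.tolist()}")
    chi2, p, dof, _ = chi2_contingency(table, correction=True)
    folds = (
        table[0, 0] / table[0, 1] if table[0, 1] else float("inf"),
        table[1, 0] / table[1, 1] if table[1, 1] else float("inf"),
    )
    return ContingencyResult(
        table=table,
        row_labels=("neutral", "outlier"),
        col_labels=col_labels,
        fold_ratios=folds,
        chi2=float(chi2),
        p=float(p),
        dof=int(dof),
    )


def chi2_contrast(
    diff_neutral: PairwiseLayer,
    diff_outlier: PairwiseLayer,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> ContingencyResult:
    """2x2 Yates chi-square: summed allelic differences between vs within
    ecotypes, for neutral vs outlier locus sets."""
    between = [(a, b) for a in group_a for b in group_b]
    within = list(itertools.combinations(list(group_a), 2)) + list(
        itertools.combinations(list(group_b), 2)
    )
    if not within or not between:
        raise ValueError("need at least one between-ecotype and one within-ecotype pair")
    return _yates_result(
        (_sum_over_pairs(diff_neutral, between), _sum_over_pairs(diff_neutral, within)),
        (_sum_over_pairs(diff_outlier, between), _sum_over_pairs(diff_outlier, within)),
        ("between_ecotype", "within_ecotype"),
    )


def outgroup_contrast(
    diff_neutral: PairwiseLayer,
    diff_outlier: PairwiseLayer,
    residents: Sequence[str],
    transients: Sequence[str],
    outgroups: Sequence[str],
) -> ContingencyResult:
    """2x2 Yates chi-square: resident-vs-outgroup against transient-vs-outgroup
    summed allelic differences, for neutral vs outlier locus sets."""
    if set(residents) & set(transients) or set(residents) & set(outgroups) or set(
        transients
    ) & set(outgroups):
        raise ValueError("resident, transient and outgroup sets must be disjoint")
    res_pairs = [(a, o) for a in residents for o in outgroups]
    tra_pairs = [(b, o) for b in transients for o in outgroups]
    if not res_pairs or not tra_pairs:
        raise ValueError("each group needs at least one population")
    return _yates_result(
        (_sum_over_pairs(diff_neutral, res_pairs), _sum_over_pairs(diff_neutral, tra_pairs)),
        (_sum_over_pairs(diff_outlier, res_pairs), _sum_over_pairs(diff_outlier, tra_pairs)),
        ("resident_vs_outgroup", "transient_vs_outgroup"),
    )
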
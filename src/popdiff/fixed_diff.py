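"""Reciprocally fixed differences between population pairs, with a sampling null.

A locus is a fixed difference between populations A and B when every
individual of A is homozygous for one allele and every individual of B
homozygous for the other.  Under a panmictic null, the probability that
two samples of nA and nB diploids drawn from a pool with alt frequency
p are reciprocally monomorphic is

    p^(2 nA) (1-p)^(2 nB) + (1-p)^(2 nA) p^(2 nB),

and the count of fixed differences over a locus set is Poisson-binomial
with those per-locus probabilities.  The upper tail of that count
distribution gives the significance of the observed number of fixed
differences "beyond sampling effects".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationMap


@dataclass
class FixedDiffReport:
    pop_a: str
    pop_b: str
    locus_set: str
    fixed_ids: list[str]
    observed: int
    null_probs: np.ndarray
    expected: float
    tail_p: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.tail_p <= self.alpha


def _pop_rows(matrix: GenotypeMatrix, popmap: PopulationMap, pop: str) -> np.ndarray:
    samples = set(popmap.samples_of(pop))
    if not samples:
        raise ValueError(f"unknown or empty population {pop!r}")
    return np.array([i for i, s in enumerate(matrix.samples) if s in samples], dtype=int)


def find_fixed(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    locus_idx: Optional[np.ndarray] = None,
) -> list[str]:
    """Locus ids reciprocally fixed between the two population samples."""
    sub = matrix if locus_idx is None else matrix.take_loci(locus_idx)
    rows_a = _pop_rows(sub, popmap, pop_a)
    rows_b = _pop_rows(sub, popmap, pop_b)
    da, db = sub.dosage[rows_a], sub.dosage[rows_b]
    if (da < 0).any() or (db < 0).any():
        raise ValueError("fixed differences require a complete-case matrix")
    a0 = (da == 0).all(axis=0)
    a2 = (da == 2).all(axis=0)
    b0 = (db == 0).all(axis=0)
    b2 = (db == 2).all(axis=0)
    fixed = (a0 & b2) | (a2 & b0)
    return list(sub.loci.loc[fixed, "id"])


def fixation_null_probability(
    pooled_alt_count: int, total_alleles: int, n_a: int, n_b: int
) -> float:
    """Reciprocal-fixation probability for a panmictic pool (0 if monomorphic)."""
    if pooled_alt_count <= 0 or pooled_alt_count >= total_alleles:
        return 0.0
    p = pooled_alt_count / total_alleles
    return float(p ** (2 * n_a) * (1 - p) ** (2 * n_b) + (1 - p) ** (2 * n_a) * p ** (2 * n_b))


def poisson_binomial_tail(probs: Sequence[float], k: int) -> float:
    """P(X >= k) for a sum of independent Bernoulli(p_i).

    Exact dynamic programming for up to 10,000 terms; a Poisson
    approximation with rate sum(p_i) beyond that.
    """
    probs = np.asarray(probs, dtype=float)
    if k <= 0:
        return 1.0
    if len(probs) < k:
        return 0.0
    if len(probs) > 10_000:
        from scipy.stats import poisson

        return float(poisson.sf(k - 1, probs.sum()))
    dist = np.array([1.0])
    for p in probs:
        new = np.zeros(len(dist) + 1)
        new[: len(dist)] += dist * (1.0 - p)
        new[1:] += dist * p
        dist = new
    return float(dist[k:].sum())


def test_pair(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    locus_idx: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    locus_set: str = "all",
) -> FixedDiffReport:
    """Observed vs expected fixed differences for one population pair."""
    sub = matrix if locus_idx is None else matrix.take_loci(locus_idx)
    fixed_ids = find_fixed(sub, popmap, pop_a, pop_b)
    rows_a = _pop_rows(sub, popmap, pop_a)
    rows_b = _pop_rows(sub, popmap, pop_b)
    union = np.concatenate([rows_a, rows_b])
    alt = sub.dosage[union].sum(axis=0)
    total = 2 * len(union)
    probs = np.array(
        [fixation_null_probability(int(c), total, len(rows_a), len(rows_b)) for c in alt]
    )
    observed = len(fixed_ids)
    tail = poisson_binomial_tail(probs, observed) if observed > 0 else 1.0
    return FixedDiffReport(
        pop_a=pop_a,
        pop_b=pop_b,
        locus_set=locus_set,
        fixed_ids=fixed_ids,
        observed=observed,
        null_probs=probs,
        expected=float(probs.sum()),
        tail_p=float(tail),
        alpha=alpha,
    )


def pairwise_fixed_table(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    neutral_idx: Optional[np.ndarray] = None,
    outlier_idx: Optional[np.ndarray] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-layer pairwise fixed-difference table (outlier counts above the
    diagonal, neutral below), with significance stars from the
    Poisson-binomial test."""
    pops = popmap.populations
    out = pd.DataFrame("", index=pops, columns=pops, dtype=object)
    for i, a in enumerate(pops):
        for j, b in enumerate(pops):
            if i == j:
                continue
            idx = outlier_idx if i < j else neutral_idx
            rep = test_pair(matrix, popmap, a, b, locus_idx=idx, alpha=alpha)
            star = "*" if (rep.observed > 0 and rep.significant) else ""
            out.iloc[i, j] = f"{rep.observed}{star}"
    return out


def group_mean_percentage(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_snps: int,
) -> float:
    """Mean pairwise fixed-difference count between two population groups,
    as a percentage of the total number of SNPs surveyed."""
    vals = [counts.loc[a, b] for a in group_a for b in group_b if a != b]
    if not vals:
        raise ValueError("no population pairs between the groups")
    return float(np.mean(vals) / n_snps * 100.0)
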
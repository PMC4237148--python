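"""Per-locus and pairwise differentiation statistics.

Implements the Weir & Cockerham (1984) moment estimator of FST (theta)
from diploid dosage data, expected heterozygosity, and mean pairwise
allelic (Manhattan) differences within and between populations.

Multi-locus theta combines variance components by ratio of sums
(sum(a) / sum(a + b + c)), the standard combination used by arlequin
and the fdist family of tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap


def wc_components(dosage: np.ndarray, pop_codes: np.ndarray, n_pops: int | None = None):
    """Weir-Cockerham variance components per locus.

    Parameters
    ----------
    dosage:
        ``(n_samples, n_loci)`` alt-allele counts in {0,1,2}; no missing
        values are allowed.
    pop_codes:
        Integer population index per sample.
    n_pops:
        Number of populations (defaults to ``max(pop_codes)+1``).

    Returns
    -------
    (a, b, c):
        Arrays of length ``n_loci`` with the among-population,
        among-individual and within-individual components.
    """
    dosage = np.asarray(dosage)
    if (dosage == MISSING).any():
        raise ValueError("Weir-Cockerham components require a complete-case matrix")
    pop_codes = np.asarray(pop_codes)
    r = int(n_pops if n_pops is not None else pop_codes.max() + 1)
    n_loci = dosage.shape[1]

    n_k = np.zeros(r)
    p_k = np.zeros((r, n_loci))
    h_k = np.zeros((r, n_loci))
    for k in range(r):
        rows = pop_codes == k
        n_k[k] = rows.sum()
        if n_k[k] == 0:
            raise ValueError(f"population index {k} has no samples")
        sub = dosage[rows]
        p_k[k] = sub.sum(axis=0) / (2.0 * n_k[k])
        h_k[k] = (sub == 1).mean(axis=0)

    n_bar = n_k.mean()
    n_c = (r * n_bar - (n_k**2).sum() / (r * n_bar)) / (r - 1)
    w = n_k[:, None] / (r * n_bar)
    p_bar = (w * p_k).sum(axis=0)
    s2 = (n_k[:, None] * (p_k - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (w * h_k).sum(axis=0)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def multilocus_theta(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums multi-locus theta; monomorphic loci contribute zero terms."""
    denom = np.nansum(a + b + c)
    if denom == 0:
        return float("nan")
    return float(np.nansum(a) / denom)


@dataclass
class PairwiseLayer:
    """Symmetric population x population matrix of one statistic."""

    populations: list[str]
    values: np.ndarray
    label: str = "all"
    statistic: str = "fst"
    pvalues: Optional[np.ndarray] = None

    def get(self, pop_a: str, pop_b: str) -> float:
        i = self.populations.index(pop_a)
        j = self.populations.index(pop_b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)

    def scaled(self, factor: float) -> "PairwiseLayer":
        return PairwiseLayer(
            populations=list(self.populations),
            values=self.values * factor,
            label=self.label,
            statistic=self.statistic,
        )


def locus_summaries(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    locus_idx: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-locus pooled frequency, expected heterozygosity and global theta.

    He is computed from the pooled alt-allele frequency as 2*p*(1-p),
    the conditioning variable of the outlier scan.
    """
    sub = matrix if locus_idx is None else matrix.take_loci(locus_idx)
    if sub.n_loci == 0:
        raise ValueError("empty locus set")
    codes = popmap.pop_codes(sub.samples)
    a, b, c = wc_components(sub.dosage, codes, len(popmap.populations))
    p_hat = sub.dosage.sum(axis=0) / (2.0 * sub.n_samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(a + b + c != 0, a / (a + b + c), np.nan)
    return pd.DataFrame(
        {
            "id": sub.loci["id"].to_numpy(),
            "p_hat": p_hat,
            "he": 2.0 * p_hat * (1.0 - p_hat),
            "theta": theta,
            "a": a,
            "b": b,
            "c": c,
        }
    )


def pairwise_fst(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    locus_idx: Optional[np.ndarray] = None,
    n_permutations: int = 0,
    seed: int | None = None,
) -> PairwiseLayer:
    """Multi-locus Weir-Cockerham theta for every population pair.

    With ``n_permutations > 0`` a one-sided permutation p-value is
    attached per pair, obtained by shuffling individuals between the two
    populations: p = (#{theta_perm >= theta_obs} + 1) / (n + 1).
    """
    sub = matrix if locus_idx is None else matrix.take_loci(locus_idx)
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("pairwise theta needs at least two populations")
    codes = popmap.pop_codes(sub.samples)
    rng = np.random.default_rng(seed)

    values = np.zeros((len(pops), len(pops)))
    pvals = np.full((len(pops), len(pops)), np.nan) if n_permutations else None
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            rows = np.flatnonzero((codes == i) | (codes == j))
            pair_codes = (codes[rows] == j).astype(int)
            d = sub.dosage[rows]
            theta = multilocus_theta(*wc_components(d, pair_codes, 2))
            values[i, j] = values[j, i] = theta
            if n_permutations:
                hits = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(pair_codes)
                    t = multilocus_theta(*wc_components(d, perm, 2))
                    if t >= theta:
                        hits += 1
                p = (hits + 1) / (n_permutations + 1)
                pvals[i, j] = pvals[j, i] = p
    return PairwiseLayer(populations=list(pops), values=values, statistic="fst", pvalues=pvals)


def allelic_difference_matrix(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    locus_idx: Optional[np.ndarray] = None,
    normalize: bool = False,
) -> PairwiseLayer:
    """Mean pairwise Manhattan distance between dosage vectors.

    Entry (A, B) averages over all cross-population individual pairs;
    the diagonal averages over distinct within-population pairs and is
    NaN for populations of size one.  With ``normalize`` the distances
    are divided by the number of loci (mean per-locus difference).
    """
    from scipy.spatial.distance import cdist, pdist

    sub = matrix if locus_idx is None else matrix.take_loci(locus_idx)
    if (sub.dosage == MISSING).any():
        raise ValueError("allelic differences require a complete-case matrix")
    pops = popmap.populations
    codes = popmap.pop_codes(sub.samples)
    blocks = [sub.dosage[codes == i].astype(float) for i in range(len(pops))]

    values = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        if len(blocks[i]) < 2:
            values[i, i] = np.nan
        else:
            values[i, i] = pdist(blocks[i], metric="cityblock").mean()
        for j in range(i + 1, len(pops)):
            values[i, j] = values[j, i] = cdist(blocks[i], blocks[j], metric="cityblock").mean()
    if normalize:
        values = values / sub.n_loci
    return PairwiseLayer(populations=list(pops), values=values, statistic="allelic_diff")
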
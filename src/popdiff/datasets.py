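"""Published summary tables from a RAD-seq survey of killer whale ecotypes.

These small worked-example inputs accompany the package: pairwise FST
estimates among the six populations with more than ten sampled
individuals (positive-outlier loci above the diagonal, neutral loci
below), and pairwise counts of reciprocally fixed differences among all
nine populations (outlier counts above, neutral below), from a survey
of 3,281 biallelic SNPs in 115 individuals.

Population codes: SR southern residents, AR Alaskan residents, BS
Bering Sea residents, RU Russian residents, AT Alaskan transients, CT
Californian transients, OS North Pacific offshores, IC Iceland, MI
Marion Island.  Residents and transients are the two sympatric North
Pacific ecotypes; OS, IC and MI serve as outgroups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popgen_stats import PairwiseLayer

#: total biallelic SNPs in the survey the tables summarise
N_SNPS_SURVEY = 3281

#: diploid sample size per population
SAMPLE_SIZES = {
    "SR": 13, "AR": 17, "BS": 13, "RU": 9, "OS": 7,
    "AT": 21, "CT": 16, "IC": 6, "MI": 13,
}

#: ecotype membership of each population
ECOTYPE_GROUPS = {
    "resident": ["SR", "AR", "BS", "RU"],
    "transient": ["AT", "CT"],
    "outgroup": ["OS", "IC", "MI"],
}

_FST_POPS = ["SR", "AR", "BS", "AT", "CT", "MI"]

# outlier loci above the diagonal, neutral loci below
_FST_TABLE = np.array(
    [
        [0.0,     0.2475,  0.21784, 0.72847, 0.73832, 0.79715],
        [0.1632,  0.0,     0.05128, 0.67336, 0.6764,  0.73618],
        [0.1363,  0.04735, 0.0,     0.64762, 0.64937, 0.71197],
        [0.29719, 0.26584, 0.23356, 0.0,     0.05099, 0.31034],
        [0.29339, 0.25936, 0.22429, 0.0346,  0.0,     0.25045],
        [0.33442, 0.30703, 0.27442, 0.17709, 0.15502, 0.0],
    ]
)

_FIXED_POPS = ["SR", "AR", "BS", "RU", "OS", "AT", "CT", "IC", "MI"]

# fixed-difference counts: outlier loci above the diagonal, neutral below
_FIXED_TABLE = np.array(
    [
        [0, 0, 0, 0, 8, 7, 5, 15, 9],
        [0, 0, 0, 0, 5, 3, 2, 12, 6],
        [0, 0, 0, 0, 5, 3, 2, 9, 5],
        [0, 0, 0, 0, 4, 3, 2, 7, 4],
        [5, 1, 0, 0, 0, 1, 1, 7, 2],
        [0, 0, 0, 0, 0, 0, 0, 1, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0],
        [6, 4, 3, 3, 2, 0, 0, 0, 0],
        [2, 0, 0, 0, 0, 0, 0, 0, 0],
    ],
    dtype=float,
)


def killerwhale_fst_table() -> pd.DataFrame:
    """Raw two-layer pairwise FST matrix (outlier upper / neutral lower)."""
    return pd.DataFrame(_FST_TABLE.copy(), index=_FST_POPS, columns=_FST_POPS)


def killerwhale_fst_layer(which: str) -> PairwiseLayer:
    """Symmetric FST layer extracted from one triangle of the table.

    Parameters
    ----------
    which:
        ``"outlier"`` for the upper triangle or ``"neutral"`` for the
        lower triangle.
    """
    if which not in ("outlier", "neutral"):
        raise ValueError("which must be 'outlier' or 'neutral'")
    n = len(_FST_POPS)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = _FST_TABLE[i, j] if which == "outlier" else _FST_TABLE[j, i]
            values[i, j] = values[j, i] = v
    return PairwiseLayer(populations=list(_FST_POPS), values=values, label=which, statistic="fst")


def killerwhale_fixed_differences(which: str) -> pd.DataFrame:
    """Symmetric pairwise fixed-difference counts for one locus layer."""
    if which not in ("outlier", "neutral"):
        raise ValueError("which must be 'outlier' or 'neutral'")
    n = len(_FIXED_POPS)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = _FIXED_TABLE[i, j] if which == "outlier" else _FIXED_TABLE[j, i]
            values[i, j] = values[j, i] = v
    return pd.DataFrame(values, index=_FIXED_POPS, columns=_FIXED_POPS)
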
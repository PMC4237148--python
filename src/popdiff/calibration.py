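"""Calibration experiments for the outlier scan under known truth.

Two standing experiments document the scan's operating characteristics
at the scale of the motivating study (9 populations, 115 individuals,
~3,000 SNPs, 50,000-locus envelopes):

- **False-positive calibration**: pure-null datasets drawn from the
  scan's own generative family (nine exchangeable populations, drift
  F = 0.05, no planted selection).  The fraction of loci labelled
  non-neutral estimates the realized false-flag rate, which FDR control
  should keep at or below the nominal level.
- **Power / recovery**: the hierarchical study design with 5% of loci
  planted at ecotype-level F = 0.5 over a neutral F = 0.05.  Recovery
  is the fraction of planted loci labelled positive; it is compared
  with the false-positive rate among truly neutral loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, PopulationMap
from .outlier_scan import classify, iterate_baseline, simulate_envelope
from .popgen_stats import locus_summaries, multilocus_theta
from .synthetic_data import DEFAULT_SAMPLE_SIZES, SimulationConfig, simulate_dataset


def null_study_config(seed: int, n_loci: int = 3000) -> SimulationConfig:
    """Pure-null study: nine exchangeable populations at the observed sizes.

    One population per ecotype with no within-ecotype drift makes the
    generative model exactly the island-model family the envelope
    simulates, so deviations measure the scan itself rather than model
    mismatch.
    """
    return SimulationConfig(
        n_ecotypes=9,
        populations_per_ecotype=1,
        samples_per_population=DEFAULT_SAMPLE_SIZES,
        n_neutral=n_loci,
        n_positive=0,
        n_balancing=0,
        n_fixed=0,
        f_ecotype_neutral=0.05,
        f_ecotype_positive=0.5,
        f_population=0.0,
        seed=seed,
    )


def power_study_config(seed: int, n_loci: int = 3000, planted_fraction: float = 0.05) -> SimulationConfig:
    """Hierarchical study design with 5% planted positively selected loci."""
    n_positive = int(round(n_loci * planted_fraction))
    return SimulationConfig(
        samples_per_population=DEFAULT_SAMPLE_SIZES,
        n_neutral=n_loci - n_positive,
        n_positive=n_positive,
        n_balancing=0,
        n_fixed=0,
        f_ecotype_neutral=0.05,
        f_ecotype_positive=0.5,
        f_population=0.02,
        seed=seed,
    )


@dataclass
class FdrCalibrationResult:
    fractions: list[float]
    fdr: float

    @property
    def mean_fraction(self) -> float:
        return float(np.mean(self.fractions))


def fdr_calibration(
    n_replicates: int = 20,
    n_loci: int = 3000,
    n_sims: int = 50_000,
    fdr: float = 0.1,
    seed: int = 0,
) -> FdrCalibrationResult:
    """Fraction of loci flagged non-neutral on pure-null datasets.

    Each replicate simulates a fresh null dataset, builds one envelope
    calibrated to that dataset's observed mean FST, and classifies.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_replicates) % (2**31)
    fractions = []
    for rep in range(n_replicates):
        cfg = null_study_config(int(child_seeds[2 * rep]), n_loci=n_loci)
        matrix, popmap, truth = simulate_dataset(cfg)
        neutral_ids = truth[truth == "neutral"].index
        idx = matrix.locus_index(neutral_ids)
        summaries = locus_summaries(matrix, popmap, locus_idx=idx)
        target = multilocus_theta(
            summaries["a"].to_numpy(), summaries["b"].to_numpy(), summaries["c"].to_numpy()
        )
        sizes = [len(popmap.samples_of(p)) for p in popmap.populations]
        envelope = simulate_envelope(
            max(0.0, target), sizes, n_sims=n_sims, seed=int(child_seeds[2 * rep + 1])
        )
        cls = classify(summaries, envelope, fdr=fdr)
        fractions.append(float((cls.table["label"] != "neutral").mean()))
    return FdrCalibrationResult(fractions=fractions, fdr=fdr)


@dataclass
class PowerResult:
    planted_positive_rate: float
    neutral_positive_rate: float
    n_planted: int
    n_neutral: int
    baseline_mean_fst: float
    iterations: int

    @property
    def fold(self) -> float:
        if self.neutral_positive_rate == 0:
            return float("inf")
        return self.planted_positive_rate / self.neutral_positive_rate


def power_recovery(
    n_loci: int = 3000,
    n_sims: int = 50_000,
    fdr: float = 0.1,
    seed: int = 0,
) -> PowerResult:
    """Recovery of planted selected loci by the full iterated-baseline scan."""
    ss = np.random.SeedSequence(seed)
    s_data, s_scan = (int(x) for x in ss.generate_state(2) % (2**31))
    cfg = power_study_config(s_data, n_loci=n_loci)
    matrix, popmap, truth = simulate_dataset(cfg)
    cls, baseline = iterate_baseline(
        matrix, popmap, fdr=fdr, n_sims=n_sims, seed=s_scan
    )
    labels = cls.labels.loc[matrix.loci["id"]]
    truth_aligned = truth.loc[matrix.loci["id"]]
    planted = truth_aligned == "positive"
    neutral = truth_aligned == "neutral"
    return PowerResult(
        planted_positive_rate=float((labels[planted] == "positive").mean()),
        neutral_positive_rate=float((labels[neutral] == "positive").mean()),
        n_planted=int(planted.sum()),
        n_neutral=int(neutral.sum()),
        baseline_mean_fst=baseline,
        iterations=cls.iterations,
    )
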
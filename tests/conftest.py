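from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popdiff.genotype_io import GenotypeMatrix, PopulationMap
from popdiff.synthetic_data import SimulationConfig, simulate_dataset


def make_matrix(dosage, pop_of_sample, positions=None, contig="chr1"):
    """Build a GenotypeMatrix + PopulationMap from a dosage array and labels.

    ``pop_of_sample`` maps each row to a population name; ecotypes default
    to one ecotype per population (``eco_<pop>``) unless given as
    ``(population, ecotype)`` tuples.
    """
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_loci = dosage.shape
    if positions is None:
        positions = np.arange(1, n_loci + 1) * 1000
    samples = [f"s{i + 1}" for i in range(n_samples)]
    rows = []
    for s, p in zip(samples, pop_of_sample):
        if isinstance(p, tuple):
            pop, eco = p
        else:
            pop, eco = p, f"eco_{p}"
        rows.append({"sample": s, "population": pop, "ecotype": eco})
    loci = pd.DataFrame(
        {
            "id": [f"{contig}_{p}" for p in positions],
            "contig": contig,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "is_snp": True,
            "is_biallelic": True,
            "mean_dp": np.nan,
        }
    )
    matrix = GenotypeMatrix(samples=samples, loci=loci, dosage=dosage)
    popmap = PopulationMap(table=pd.DataFrame(rows))
    return matrix, popmap


@pytest.fixture(scope="session")
def planted_dataset():
    """Mid-sized synthetic dataset with all four locus classes planted."""
    cfg = SimulationConfig(
        n_neutral=500, n_positive=40, n_balancing=20, n_fixed=10, seed=20240901
    )
    matrix, popmap, truth = simulate_dataset(cfg)
    return cfg, matrix, popmap, truth
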
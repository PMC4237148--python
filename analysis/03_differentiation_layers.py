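#!/usr/bin/env python
"""Pairwise differentiation layers on neutral vs outlier locus sets.

Computes multi-locus Weir-Cockerham FST and mean pairwise allelic
differences for every population pair, separately over the neutral and
the positively selected locus sets from the scan, mirroring the
two-layer (upper/lower diagonal) presentation of the motivating study.
Writes one TSV per layer under results/layers/.
"""

import argparse
from pathlib import Path

import pandas as pd

from popdiff.genotype_io import filter_snps, read_popmap, read_vcf
from popdiff.popgen_stats import allelic_difference_matrix, pairwise_fst


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--scan-dir", type=Path, default=Path("results/scan"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/layers"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    matrix = read_vcf(args.data_dir / "genotypes.vcf")
    matrix, _ = filter_snps(matrix)
    popmap = read_popmap(args.data_dir / "popmap.tsv", matrix)
    labels = pd.read_csv(args.scan_dir / "classification.tsv", sep="\t")

    for key, label in (("neutral", "neutral"), ("outlier", "positive")):
        idx = matrix.locus_index(labels.loc[labels["label"] == label, "id"])
        if len(idx) == 0:
            print(f"no {label} loci; skipping {key} layer")
            continue
        fst = pairwise_fst(matrix, popmap, locus_idx=idx)
        diff = allelic_difference_matrix(matrix, popmap, locus_idx=idx)
        fst.to_frame().to_csv(args.out_dir / f"fst_{key}.tsv", sep="\t", float_format="%.5f")
        diff.to_frame().to_csv(args.out_dir / f"alleldiff_{key}.tsv", sep="\t", float_format="%.3f")
        print(f"{key} layer ({len(idx)} loci): "
              f"mean pairwise FST = {fst.values[fst.values != 0].mean():.4f}")


if __name__ == "__main__":
    main()
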
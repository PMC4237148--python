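#!/usr/bin/env python
"""Between- vs within-ecotype contrasts, on synthetic layers and on the
published killer-whale FST table.

Part 1 reruns the headline worked example on the published 6x6 FST
matrix (outlier upper / neutral lower triangle): the 24 between/within
ratio pairs per layer, their Mann-Whitney comparison.  Part 2 applies
the same contrasts to the synthetic scan layers, including the Yates
chi-square contingency contrasts of allelic differences.  Writes
results/contrasts/contrasts.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from popdiff import datasets
from popdiff.ecotype_contrast import chi2_contrast, mann_whitney, outgroup_contrast, ratio_set
from popdiff.genotype_io import filter_snps, read_popmap, read_vcf
from popdiff.popgen_stats import allelic_difference_matrix, pairwise_fst


def published_worked_example() -> dict:
    residents, transients = ["SR", "AR", "BS"], ["AT", "CT"]
    out = {}
    ratios = {}
    for which in ("neutral", "outlier"):
        rc = ratio_set(datasets.killerwhale_fst_layer(which), residents, transients)
        ratios[which] = rc
        out[which] = {"n": rc.n, "mean": round(rc.mean, 2), "min": round(rc.min, 2),
                      "max": round(rc.max, 2)}
    mw = mann_whitney(ratios["neutral"].ratios, ratios["outlier"].ratios)
    out["mann_whitney"] = {"u": mw.u, "z": round(mw.z, 2), "p": round(mw.p, 3)}
    return out


def synthetic_contrasts(data_dir: Path, scan_dir: Path) -> dict:
    matrix = read_vcf(data_dir / "genotypes.vcf")
    matrix, _ = filter_snps(matrix)
    popmap = read_popmap(data_dir / "popmap.tsv", matrix)
    labels = pd.read_csv(scan_dir / "classification.tsv", sep="\t")

    layers = {}
    for key, label in (("neutral", "neutral"), ("outlier", "positive")):
        idx = matrix.locus_index(labels.loc[labels["label"] == label, "id"])
        layers[key] = {
            "fst": pairwise_fst(matrix, popmap, locus_idx=idx),
            "diff": allelic_difference_matrix(matrix, popmap, locus_idx=idx),
        }
    ecos = popmap.ecotypes()
    res = popmap.populations_of_ecotype(ecos[0])
    tra = popmap.populations_of_ecotype(ecos[1])
    outg = popmap.populations_of_ecotype(ecos[2]) if len(ecos) > 2 else []

    out = {"residents": res, "transients": tra, "outgroups": outg, "ratio": {}}
    ratios = {}
    for key in ("neutral", "outlier"):
        rc = ratio_set(layers[key]["fst"], res, tra)
        ratios[key] = rc
        out["ratio"][key] = {"n": rc.n, "mean": round(rc.mean, 3),
                             "min": round(rc.min, 3), "max": round(rc.max, 3)}
    mw = mann_whitney(ratios["neutral"].ratios, ratios["outlier"].ratios)
    out["mann_whitney"] = {"z": round(mw.z, 3), "p": round(mw.p, 4)}
    c1 = chi2_contrast(layers["neutral"]["diff"], layers["outlier"]["diff"], res, tra)
    out["between_within"] = {
        "table": c1.table.tolist(),
        "fold_ratios": [float(round(f, 2)) for f in c1.fold_ratios],
        "chi2": round(c1.chi2, 2),
        "p": c1.p,
    }
    if outg:
        c2 = outgroup_contrast(layers["neutral"]["diff"], layers["outlier"]["diff"], res, tra, outg)
        out["outgroup"] = {
            "table": c2.table.tolist(),
            "fold_ratios": [float(round(f, 2)) for f in c2.fold_ratios],
            "chi2": round(c2.chi2, 2),
            "p": c2.p,
        }
    return out


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--scan-dir", type=Path, default=Path("results/scan"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/contrasts"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    report = {
        "published_worked_example": published_worked_example(),
        "synthetic": synthetic_contrasts(args.data_dir, args.scan_dir),
    }
    (args.out_dir / "contrasts.json").write_text(json.dumps(report, indent=2) + "\n")

    pub = report["published_worked_example"]
    print("published FST table: outlier ratio mean "
          f"{pub['outlier']['mean']} (range {pub['outlier']['min']}-{pub['outlier']['max']}), "
          f"neutral mean {pub['neutral']['mean']}; Mann-Whitney Z = {pub['mann_whitney']['z']}, "
          f"p = {pub['mann_whitney']['p']}")
    syn = report["synthetic"]
    print("synthetic layers: outlier ratio mean "
          f"{syn['ratio']['outlier']['mean']} vs neutral {syn['ratio']['neutral']['mean']}; "
          f"between/within fold {syn['between_within']['fold_ratios']} "
          f"(chi2 = {syn['between_within']['chi2']})")


if __name__ == "__main__":
    main()
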
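# popdiff

Neutral versus selected population differentiation for multi-population
SNP data, built around the study design of killer whale (*Orcinus
orca*) ecotypes: sympatric fish-eating "residents" and mammal-eating
"transients" in the North Pacific plus outgroup populations, genotyped
at a few thousand genomewide biallelic SNPs.

The package is for population geneticists who want to ask, from a VCF
and a population map: which loci differentiate more (or less) than
neutral drift can explain, do the putatively selected loci structure
populations differently from the neutral ones, and are the genes near
them functionally coherent?

## What it computes

**FST outlier scan (FDIST-style).** Per-locus Weir & Cockerham (1984)
θ and pooled heterozygosity He = 2p̂(1−p̂) are compared to a simulated
neutral envelope. The envelope draws ancestral frequencies p ~ U(0.01,
0.99), population frequencies from the Balding–Nichols distribution
Beta(p(1−F)/F, (1−p)(1−F)/F), and binomial genotypes at the observed
sample sizes; the drift parameter F is calibrated by bisection until
the mean simulated θ (ratio of variance-component sums) matches the
observed neutral baseline to within 10⁻³. Conditional tail
probabilities P(θ_sim ≥ θ_obs | He bin) are controlled with
Benjamini–Hochberg at FDR 0.1 separately for the upper (positive
selection) and lower (balancing) tail, and the neutral baseline is
iterated: flagged loci are excluded, the baseline mean recomputed, the
envelope recalibrated, until the neutral set stabilises.

**Fixed differences.** A locus is a fixed difference between
populations A and B when the two samples are reciprocally monomorphic.
Under a panmictic null with pooled alt frequency p̂ the per-locus
probability is p̂^2nA(1−p̂)^2nB + (1−p̂)^2nA p̂^2nB, and the observed
count over a locus set is tested against the Poisson-binomial upper
tail (exact dynamic programming).

**Ecotype contrasts.** For two ecotype groups, every ratio
FST(between-ecotype pair) / FST(within-ecotype pair) is formed (full
Cartesian product); neutral and outlier ratio sets are compared with a
Mann–Whitney U test (midrank ties, tie-corrected variance, continuity
correction; exact enumeration for small sets), and 2×2 Yates-corrected
χ² tables contrast summed allelic differences between vs within
ecotypes, or against outgroups.

**Annotation enrichment.** SNPs link to genes within 5 kb; term
overrepresentation in candidate gene lists is tested per term with
two-tailed Fisher's exact tests, BH-corrected, with a negative control
of 10 random same-length lists drawn from neutral-locus genes.

**Demographic units.** Diffusion-scaled parameters convert to natural
units: Nref = θ/(4μL), years = 2·Nref·T·g, and the expected sequence
divergence 2μT/g with μ = 2.34×10⁻⁸ /nt/generation, L = 1.45 Mb,
g = 25.7 y.

A synthetic-data generator (`popdiff.synthetic_data`) produces the
whole study design with known truth — hierarchical Balding–Nichols
drift (ecotype level over population level), planted positive /
balancing / reciprocally fixed loci, and a gene/term track enriched
near selected loci — so every stage is testable against planted truth.

## Worked example

The package ships the published pairwise FST table from the killer
whale survey (six populations with N > 10; outlier loci above the
diagonal, neutral below) as `popdiff.datasets`:

```python
from popdiff import datasets
from popdiff.ecotype_contrast import ratio_set, mann_whitney

res, tra = ["SR", "AR", "BS"], ["AT", "CT"]
r_out = ratio_set(datasets.killerwhale_fst_layer("outlier"), res, tra)
r_neu = ratio_set(datasets.killerwhale_fst_layer("neutral"), res, tra)
print(r_out.n, round(r_out.mean, 2), round(r_out.max, 2))  # 24 8.18 14.48
print(r_neu.n, round(r_neu.mean, 2), round(r_neu.max, 2))  # 24 4.16 8.59
mw = mann_whitney(r_neu.ratios, r_out.ratios)
print(round(mw.z, 2), round(mw.p, 3))                      # -2.96 0.003
```

Each of the 24 values per layer is the FST of one resident–transient
population pair divided by the FST of one within-ecotype pair. The
outlier loci show roughly twice the between/within contrast of the
neutral loci (mean ratio 8.18 vs 4.16), and the rank test says the two
ratio sets differ (Z = −2.96, two-sided p ≈ 0.003): selected loci
differentiate ecotypes disproportionately.

## Analysis scripts

The full synthetic study runs as numbered drivers (each writes under
`results/`):

```bash
python analysis/01_simulate_dataset.py --seed 1   # 115 samples x 3000 SNPs
python analysis/02_scan_outliers.py    --seed 1   # envelope scan, FDR 0.1
python analysis/03_differentiation_layers.py      # FST / allelic-diff layers
python analysis/04_ecotype_contrasts.py           # ratio sets, U test, chi^2
python analysis/05_fixed_differences.py           # pairwise fixed-diff table
python analysis/06_enrichment.py       --seed 1   # Fisher terms + control
python analysis/07_demographic_units.py           # unit conversions
```

With the default seed the scan recovers 91/150 planted positively
selected loci and all 30 planted fixed loci at a 2.7% false-positive
rate, and the enrichment stage flags exactly the two planted terms
(smallest adjusted p ≈ 0.003) while 0/10 random neutral gene lists
produce any significant term.

There is also a `popdiff` CLI (`simulate`, `filter`, `scan`,
`contrast`, `fixed`, `enrich`, `units`, `run`) wrapping the same
library, and `popdiff.pipeline.run_pipeline` for an end-to-end run from
one config file with a checksummed, seed-reproducible artifact bundle.

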
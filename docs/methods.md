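# Methods

This note documents the statistical models, numerical choices and known
limitations of popdiff. It is written for a user deciding whether the
defaults fit their data, and for a maintainer wondering why something
is the way it is.

## Estimators

**Weir–Cockerham θ.** All FST values are the Weir & Cockerham (1984)
moment estimator computed from diploid dosages: per-locus variance
components a (among populations), b (among individuals within
populations) and c (within individuals), with θ = a/(a+b+c).
Multi-locus and pairwise values combine components by ratio of sums,
Σa / Σ(a+b+c) — the combination used by arlequin and the fdist family.
Negative per-locus θ values are reported as computed, not clamped;
monomorphic loci (a+b+c = 0) propagate NaN and are excluded from
multi-locus sums. A pairwise θ is identical to the multi-population
formula restricted to the two populations (tested).

**Heterozygosity.** He = 2p̂(1−p̂) from the pooled alt-allele frequency
over all included samples. This is the conditioning variable of the
outlier scan, chosen because the neutral θ distribution varies strongly
with allele frequency.

**Allelic differences.** "Nucleotide differences" between individuals
are implemented as the Manhattan distance between dosage vectors
restricted to a locus set (each locus contributes 0–2). Between-
population entries average over all cross-population individual pairs;
diagonal entries over distinct within-population pairs (undefined, NaN,
for populations of one). Both the raw mean distance and a
per-locus-normalised variant are emitted, since either convention is
defensible for heat-map style comparisons.

## The neutral envelope and outlier classification

The null model is an exchangeable island-model stand-in: ancestral
frequency p ~ Uniform(0.01, 0.99); one Balding–Nichols draw
Beta(p(1−F)/F, (1−p)(1−F)/F) per population; binomial allele sampling
at the observed per-population sample sizes; (He, θ) computed by the
same code path as the observed data. Monomorphic simulated loci are
discarded and topped up. This replaces a coalescent island-model
simulator: it matches the target first moment exactly, has closed-form
drift moments (E = p, Var = F·p(1−p), verified by test), and is fast
enough to rebuild per baseline iteration. Results on real data may
differ in detail from coalescent-based tools, whose null includes
migration-history correlations this model lacks.

**Bisection calibration.** F is calibrated so the ratio-of-sums mean
simulated θ matches the observed neutral baseline within 10⁻³
(internally the loop stops at half that). The mean-θ-versus-F curve is
made deterministic and monotone with common random numbers: a fixed
matrix of uniforms is pushed through the Balding–Nichols quantile
function at each candidate F, and fixed uniforms drive the binomial
genotype draws. Bisection runs coarse steps on a 10,000-locus prefix
until the bracket is ≤0.01 wide, then full-sample steps after widening
the bracket by 0.01 on each side (the coarse and full curves differ by
a Monte-Carlo offset of order 10⁻³, so the full-sample root can sit
just outside the coarse bracket). The accepted full-sample evaluation
*is* the envelope, so the achieved mean equals the converged value;
non-convergence raises with the full bracketing trace.

**Tail probabilities and FDR.** Simulated loci are split into 50
equal-count He bins (quantile edges; configurable). An observed locus
takes the empirical upper-tail probability (r + 0.5)/(m + 1) in its
bin, where r counts simulated θ at least as large — the half-count
convention keeps p strictly inside (0,1) while preserving ranking; the
lower tail is symmetric. Loci with He outside the simulated range are
assigned to the nearest edge bin and logged. Benjamini–Hochberg at the
stated FDR (default 0.1) runs separately on the upper tail (label
"positive") and lower tail ("balancing") because the two candidate sets
are reported separately downstream; the rare locus rejected in both
takes the side with the smaller raw probability. Loci whose θ exceeds
every simulated value in their bin (r = 0, outlier probability 1 at the
simulation resolution) are flagged "best supported" and are the
candidate set passed to annotation.

With 50 bins the smallest attainable tail probability is roughly
0.5/(n_sims/50 + 1), so the scan needs n_sims large relative to the bin
count before BH can reject anything (≈10⁴ minimum; the default is
5×10⁴). Balancing-selection detection is intrinsically weak under this
null: at moderate baseline F the envelope retains substantial mass near
θ = 0, so even loci with no drift at all rarely reach the lower-tail
floor. The planted balancing class in the synthetic study is typically
not recovered, and the tests assert power only for the positive class.

**Baseline iteration.** The neutral baseline starts as the all-locus
mean θ; after each classification the mean is recomputed over the
currently neutral loci, the envelope recalibrated (the random-number
stream is held fixed across iterations so only the target moves), and
loci reclassified, until the neutral set repeats exactly (converged) or
a previously seen neutral set recurs (a provable cycle among borderline
loci; the scan returns the last state with a non-convergence flag).
Near the BH rejection boundary one or two loci can toggle indefinitely,
so the flag is informational — the baseline typically moves by <10⁻³
between cycle states.

## Fixed differences

A locus is a fixed difference between population samples A and B iff
every A individual is homozygous for one allele and every B individual
for the other. The sampling null assumes panmixia at the pooled alt
frequency p̂; the per-locus reciprocal-fixation probability is
p̂^2nA(1−p̂)^2nB + (1−p̂)^2nA·p̂^2nB (zero for monomorphic pools, by
contract), and the count over a locus set is Poisson-binomial over the
per-locus probabilities. The tail P(X ≥ observed) is computed by exact
O(L²) dynamic programming up to 10⁴ loci and by a Poisson approximation
with rate Σpᵢ beyond. No multiple-testing correction is applied across
population pairs by default; each pair is reported at its own alpha
(0.05), with counts reported separately for the neutral and outlier
locus sets.

## Ecotype contrasts

The ratio statistic takes a pairwise FST layer and two ecotype groups:
between-pairs are the full cross product of group A and group B
populations, within-pairs the within-group pairs of both, and the ratio
set is the full Cartesian product (N = |between| × |within|; the ratios
are correlated by construction, which the Mann–Whitney comparison of
two such sets inherits — the published analysis has the same property).
It is scale-invariant in the layer.

Mann–Whitney U uses midranks for ties; the normal approximation uses
the tie-corrected variance mn/12·((N+1) − Σ(t³−t)/(N(N−1))) and a ±0.5
continuity correction, with Z negative when the first set is
stochastically smaller. When m·n ≤ 400 and there are no ties, the exact
two-sided p comes from the Gaussian-binomial count distribution of U
(two-sided p = 2·min(lower, upper), capped at 1); with ties or larger
samples the normal approximation is reported. The degenerate all-tied
case returns Z = 0, p = 1.

The χ² contrasts summarise allelic-difference layers as 2×2 tables:
rows neutral/outlier, columns either (between-ecotype, within-ecotype)
or (resident-vs-outgroup, transient-vs-outgroup) summed mean distances,
rounded to integer counts, with Yates-corrected χ² on 1 d.f. and
per-row fold ratios. Building counts from summed mean distances is an
interpretation — the analysis that motivated it does not spell out its
cell construction — so these χ² values characterise direction and
strength on synthetic data rather than reproduce any published
statistic.

## Annotation enrichment

A SNP links to a gene when at most `window` (default 5,000) bases
separate the SNP position from the gene span — the distance counts
intervening bases, so a span starting 5,001 positions downstream is
exactly 5,000 bases away and is linked, and a SNP inside a span is
linked at any window. Linkage is implemented with an interval tree and
cross-checked against an exhaustive gap-enumeration oracle. Enrichment
per term is the two-tailed Fisher exact test on [[k, n−k],
[K−k, (N−n)−(K−k)]] (candidates must be a subset of the background;
duplicates removed), BH-corrected across terms; terms are treated as
flat labels with no ontology-graph propagation. The negative control
draws 10 random gene lists of candidate length from the neutral-locus
genes, seed-reproducibly, and reports how many lists yield any
significant term.

## Demographic unit conversions

With μ the per-generation mutation rate, L the surveyed sequence
length and g the generation time: Nref = θ/(4μL); a time in units of
2·Nref generations converts to years as 2·Nref·T·g; symmetric scaled
migration M = 2·Nref·m converts to M·ν/2 immigrants per generation
into a population of scaled size ν (the convention is stated in output
headers because tools differ). Expected neutral sequence divergence
between two species separated T years ago is 2μT/g — substitutions
accumulate on both lineages. Defaults are the killer whale constants:
μ = 2.34×10⁻⁸, L = 1.45 Mb, g = 25.7 y, T = 10 My, which give 1.82%.

## The synthetic-data generator

The generator emulates the killer whale survey: 9 populations in 3
ecotype groups with the observed sample sizes (13, 17, 13, 9, 7, 21,
16, 6, 13 — 115 diploids), ~3,000 biallelic SNPs, no missing
genotypes. Drift is hierarchical Balding–Nichols: ancestral
p ~ Uniform(0.05, 0.95) (avoiding quasi-monomorphic loci, mimicking
variable-SNP ascertainment), an ecotype-level draw with
F_ecotype, then a population-level draw with F_population, then
binomial(2, p_pop) genotypes. Defaults: F_ecotype 0.05 for neutral loci
and 0.5 for the positive class, F_population 0.02; class counts
2700/150/120/30 (neutral/positive/balancing/fixed), roughly one tenth
of loci non-neutral. Balancing loci pin p near 0.5 with zero drift at
both levels (suppressed differentiation at high He); fixed loci set the
alternate allele homozygous throughout one designated ecotype and
absent elsewhere. Loci that come out monomorphic are redrawn (at most
100 rounds, then error). Loci sit at distinct uniform positions on one
50 Mb contig — sparse enough that 5 kb windows only occasionally span
a neighbouring locus's gene, as for reduced-representation loci on a
mammalian genome.

The annotation generator places a gene (default 2 kb) centred on a
configurable fraction of loci and tags genes with terms from a
40-term background pool; genes at positive/fixed loci carry one of the
designated "enriched" terms with probability 0.8 versus 0.1 elsewhere.

What the generator does **not** emulate: linkage disequilibrium and
physical linkage of selection signals (every locus is independent),
coalescent genealogy and migration (drift is exchangeable
Balding–Nichols, not the species' actual branching history), sequencing
error, missing data, and ascertainment beyond the ancestral-frequency
bounds. Passing tests therefore demonstrate the statistics and their
calibration under the stated drift model, not robustness to realistic
LD or demography.

## Calibration experiments

Two standing experiments (`popdiff.calibration`) characterise the scan
at study scale, and the acceptance script re-runs both:

- **False-positive calibration**: 20 pure-null datasets of 3,000 loci —
  nine *exchangeable* populations (one per ecotype, F = 0.05, no
  within-ecotype drift) at the observed sample sizes — each scanned
  against a 50,000-locus envelope at FDR 0.1. The exchangeable design
  makes the generative model exactly the family the envelope simulates,
  so the flagged fraction measures the procedure, not model mismatch;
  BH on the discrete tail is conservative and the realized fraction is
  typically ~0. Hierarchically structured data violate the
  island-model null and can inflate the rate — a known property of
  FDIST-style scans, visible in the power experiment below.
- **Power / recovery**: the hierarchical study design with 5% of loci
  planted at ecotype-level F = 0.5 over neutral 0.05, scanned with the
  full iterated baseline. Typical outcome at the default scale:
  recovery ≈ 0.55–0.6 of planted loci, neutral false-positive rate
  ≈ 0.01, a ~50-fold separation.

Problem sizes in the test suite follow these conditions (3,000 loci,
50,000-locus envelopes, 20 null replicates); smaller unit tests use
reduced envelopes (4,000–10,000 loci) where only correctness, not
calibration, is at stake.

## Numerical and interface choices

- Dosage encodes the count of the VCF ALT allele; every statistic is
  invariant to ref/alt orientation (tested by flipping).
- Coverage and genotype-quality filters act on VCF annotations (FORMAT
  DP averaged per site; per-genotype GQ, dropping a locus if any
  genotype is below threshold — the strictest reading consistent with
  the complete-case rule). When the annotations are absent (synthetic
  data), those filters deactivate with a logged warning, since the
  upstream caller already enforced them. "Average coverage" is read as
  the per-site mean across samples.
- Sites where every retained rule passes but all samples are homozygous
  for one allele are removed as non-variable.
- All randomness flows through numpy Generators seeded from explicit
  integers; the pipeline derives stage seeds from one master seed and
  writes a manifest of SHA-256 checksums, so identical config + seed
  reproduces every artifact byte for byte.
- Tabular output uses a fixed float format (%.6g) so that determinism
  holds across runs at the byte level.

## Known limitations

- The envelope's island model ignores hierarchical covariance between
  populations of the same ecotype; on strongly hierarchical data the
  neutral false-positive rate exceeds the nominal FDR (≈1–3% at the
  study design's parameters) and balancing detection is weak.
- The Poisson-binomial null for fixed differences conditions on the
  pooled frequency and assumes locus independence; with few loci or
  strong LD the tail is approximate.
- Enrichment treats terms as flat labels; ontology ancestry is not
  propagated, and the background is whatever gene set the caller
  supplies.
- The Mann–Whitney exact path requires tie-free data; tied inputs fall
  back to the corrected normal approximation regardless of sample size.
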
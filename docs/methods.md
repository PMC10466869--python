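# Methods

## The two-bulk design and the ED scan

`bsascan` targets extreme-phenotype bulked-segregant designs: two pools of
individuals from the opposite tails of a quantitative phenotype are
sequenced, and per-site allele depths are compared between pools. At a locus
unlinked to the trait both pools sample the same population allele
frequency, so the expected frequency difference is zero and the observed ED
reflects only binomial sampling noise at the pool depths. Near a
trait-associated locus the tails of the phenotype distribution are enriched
for opposite alleles, the pool frequencies separate, and ED rises toward its
maximum of √2 (pools fixed for different alleles).

ED is raised to the 4th power before smoothing. Since background ED at 30X
is typically ~0.1–0.3 while true divergence approaches 1, the 4th power
shrinks noise by orders of magnitude more than signal. The ED⁴ track is then
smoothed along each chromosome and thresholded genome-wide.

## Filters ahead of the scan

Pre-scan filtering runs as an ordered cascade with per-stage accounting:

1. **Biallelic**: exactly two bases observed across both pools. Monomorphic
   and tri-/tetra-allelic sites are removed; all later frequency math uses
   the two retained bases.
2. **Frequency**: sites where either retained base reaches ≥ 95% of the
   wild-type pool are removed — a near-fixed wild-type pool carries no
   segregating contrast. The screen applies to the wild-type pool only by
   default; `screen_mut_pool=True` extends it to both pools.
3. **Depth**: either pool under 10X (over the retained bases) is removed.

Thresholds are inclusive (exactly 0.95 is filtered; depth exactly 10 is
kept). The per-sample genotype rules (used for the phenotype table, not the
scan) are likewise inclusive: depth < 5 → missing; allele frequency ≥ 0.8
for either allele → homozygous for it; otherwise heterozygous when both
alleles have ≥ 4 reads, else missing. The homozygous test compares each
allele's own frequency to 0.8 rather than the alt frequency to `1 − 0.8`,
which keeps the 0.2 boundary exact in floating point.

## Smoothing, threshold, regions, candidates

The smoother is a degree-1 LOESS written in-package: at each site the window
is its k nearest sites by genomic distance (k = ⌈span · n⌉ per chromosome,
default span 0.1, minimum 3; distance ties break toward the lower index),
the bandwidth is the window's largest distance (so the farthest neighbour
has weight zero), weights are tricube, and the weighted line is evaluated at
the site. One pass, no robustness reweighting. Fitted values are clipped at
0 (ED⁴ is non-negative; a local line can undershoot). Chromosomes with fewer
than 10 sites keep raw ED⁴ with a warning. Keeping the smoother in-package
pins the window and tie conventions so tests can compare it to an
independent brute-force weighted-least-squares evaluation to 10⁻⁹;
statsmodels' lowess (same kernel and degree) serves as a second, looser
cross-check.

The association threshold is median + 3·SD of all fitted values genome-wide
(sample SD, n − 1 denominator — pinned for tests; the choice is negligible
at scale). Maximal runs of consecutive same-chromosome sites with fitted
values at or above the threshold become associated regions; a single
sub-threshold site splits a region. Candidates are region sites with
mutant-pool non-reference allele frequency strictly above 0.75 **and** raw
ED (not ED⁴) strictly above 0.5: the candidate rule names the distance
itself, while the fitted curve uses the 4th power. "Mutation frequency" is
taken as the non-reference allele fraction in the high-phenotype pool, the
usual BSA convention.

## The simulator

`simulate_bulks` emulates the study design: two pools of `pool_size = 3`
animals, mean depth 28X (the acceptance benchmarks use 30X), 5,000
segregating sites on two 50 Mb chromosomes. Each site draws a baseline
alt-allele frequency uniformly from `baseline_maf_range = (0.1, 0.5)`. A
planted QTL at (chrom, pos, delta) pushes the pools apart by delta at its
peak, decaying linearly to zero over `linkage_window = 2 Mb` — a scale
chosen to mimic the broad linkage blocks around a causal allele when bulks
are small samples from a livestock population with long-range LD. Pool
frequencies are `p ± delta·w/2` clamped to [0, 1] (clamps logged). Per-pool
depths are independent Poisson draws; read counts are binomial in the pool
frequency. Finite-pool resampling (only 6 founder genomes per pool) is *not*
modelled, so real bulks of 3 animals are noisier than these simulations;
passing recovery tests therefore demonstrate correctness of the chain, not
field-calibrated power. Mapping bias, base-calling error, indels and
structural variants are likewise out of scope. All draws flow from one
`numpy` generator seeded once, making output byte-identical per seed.

`simulate_phenotypes` draws melatonin as
`μ + genotype shift + age shift + N(0, sd)`, floored at 0 (assay floor;
negligible at the defaults μ = 1.64 ng/mL, sd = 0.5). Defaults model a
195-animal flock with a roughly 9:1 common/rare genotype split and a
+2 ng/mL rare-genotype effect, matching the magnitude of effects the
pipeline is meant to detect; three age classes carry small shifts
(0/0.2/0.4 ng/mL).

## Enrichment

The enrichment engine is shared by GO-style and pathway-style term maps
(flat mappings; no DAG propagation). For a term with M carriers among the N
annotated background genes and m among the n annotated candidates, p is the
exact upper tail P(X ≥ m), X ~ Hypergeometric(N, M, n), computed via the
log-space survival function — no normal approximation. The background
universe is the *annotated* genes only; candidates outside it are dropped
with a logged count. Q-values are Benjamini–Hochberg across all terms with
m ≥ 1; significance is q ≤ 0.05; the rich factor is m/M. Because the test is
discrete, null calibration is slightly conservative: with term sizes of
100–400 in a 2,000-gene universe about 4% of null terms fall below p = 0.05
rather than the nominal 5%.

## Phenotype model

`fit_association` fits `Y = μ + G + P + e` by OLS with sum-to-zero
constraints on both factors and tests the genotype factor with a partial
F-test (type-II sums of squares: genotype after age). Age is categorical by
default. Genotype classes with fewer than 2 observations are dropped; with
fewer than 2 classes left the site is flagged untestable. When the data hold
a single age level the model reduces to one-way ANOVA on genotype (verified
against the closed-form F). Reported per-genotype means are raw class means;
under unbalanced age assignment these differ from the model effects — the
model contrast, not the raw-mean difference, recovers a planted effect
exactly in noiseless data. Analysis is complete-case: animals missing the
genotype or age are excluded per site.

`summarize_bins` uses left-closed, right-open intervals with the last bin
open above, and rounds percentages to one decimal (e.g. a 100/42/53 split of
195 → 51.3/21.5/27.2).

## Annotation

Candidate SNPs are classified against single-transcript gene models
(first mRNA per gene; no isoform arbitration) with precedence exonic >
splicing > UTR5/UTR3 > intronic > upstream/downstream (≤ 1 kb) > intergenic;
"splicing" is within 2 bp of an exon–intron boundary on the intron side.
Coding consequences translate the affected codon (strand- and frame-aware,
standard code) for both alleles: synonymous, non-synonymous, stop-gain,
stop-loss, with the change reported as "X/Y". A reference-base mismatch
between the site and the genome is warned, not fatal.

## Numerical and scale choices

The test and acceptance benchmarks run the full chain at 5,000 sites ×
20–40 seeds, the scale at which the simulator's properties (planted-QTL
recovery ≥ 95% of seeds at delta 0.8/30X; frequency agreement with truth at
high depth) are checked in seconds per run. One known desk-scale behaviour:
with no QTL, the fraction of sites falling inside called regions is ~1.2%
rather than < 1%. The Median + 3SD exceedance of the smoothed ED⁴ field is
controlled by the field's residual right-skew, which shrinks as windows
average more sites; at a few thousand sites per genome the windows hold only
a couple of hundred sites and the skew keeps the exceedance slightly above
1% (statsmodels' lowess reproduces the same figure). At full genome scale
(millions of sites) the field is near-Gaussian and the exceedance collapses
toward ~0.1%.

## Limitations

- Binomial pool sampling without founder resampling understates bulk noise
  for very small pools (see above).
- The threshold is genome-wide; strong QTL inflate the SD and can mask weak
  secondary QTL.
- Flat term maps only: GO ancestry and pathway topology are out of scope.
- Single-transcript annotation can misclassify sites whose isoforms disagree.
- The phenotype model is fixed-effects OLS; kinship, mixed models and
  multi-locus modelling are out of scope.
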
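# Methods

`polyselect` detects and localises human-induced polygenic selection in a
closed breeding population genotyped across consecutive birth-year
cohorts. This note describes the models, the simulator that serves as the
test bed, the numerical choices, and the known limitations.

## Generation Proxy Selection Mapping (GPSM)

Each animal's age at a fixed reference date (default: December 21 of the
last birth year) is regressed on allele dosage one variant at a time
under the linear mixed model

    y = X b + g beta + u + e,   u ~ N(0, G sigma_a^2),   e ~ N(0, I sigma_e^2)

where `G` is the genomic relationship matrix. Because `u` absorbs the
drift covariance among relatives, a variant with a significant dosage
effect `beta` on the generation proxy has changed frequency along the
pedigree faster than drift predicts — evidence of ongoing selection,
without reference to any phenotype. Multiple testing is controlled with
Benjamini–Hochberg q-values (Storey's lambda = 0.5 variant available);
q < 0.1 is the discovery rule.

Variance components are estimated by REML, profiled over the ratio
`delta = sigma_e^2 / sigma_a^2` after one eigendecomposition of `G` (the
EMMA rotation); `log10(delta)` is optimised on [-5, 8] by bounded Brent
search (xatol 1e-6). The lower bound keeps `G + delta I` invertible to
working precision for rank-deficient kernels. The default per-variant
test reuses the null-model components for every variant (P3D/EMMAX); an
exact mode re-optimises them per variant and is verified against a dense
GLS solve. Fixed effects are an intercept only (optionally sex).
Monomorphic variants yield missing p-values and are excluded from FDR.

## The Ghat composite test

For a trait (teat counts here), ridge-regression BLUP (RRBLUP) estimates
all marker effects `alpha_j` jointly, with the year-season of birth as a
fixed-effect factor (season 1 = December–February, December keeping its
calendar year; levels with fewer than 2 records are merged with the
adjacent level). The shrinkage is `lambda_r = sigma_e^2 / sigma_m^2`
with `sigma_m^2 = sigma_a^2 / sum 2p(1-p)`, variance components from the
same REML machinery. With `Delta_j` the ALT-frequency change between the
earliest and latest birth cohorts,

    Ghat = sum_j Delta_j alpha_j

is compared with a null built by permuting the effect vector across
markers (1000 permutations by default; plus-one p estimator, two-sided
on |Ghat| with the sign reported, one-sided also returned). Block
permutation (`unit='block'`) preserves local LD covariance and is
offered because marker-wise shuffling is anticonservative on dense data.

**Limitation.** In a herd with few sires the trait's genetic mean itself
drifts between the endpoint cohorts. That drift-caused genetic change is
real change and Ghat registers it, but no permutation of marker effects
can represent it, so the test over-rejects under pure drift at small Ne
and small marker counts (measured here: ~20–30% rejection at the 0.05
level on drift-only herds with Ne ≈ 170 and 5000 markers; block
permutation, LD pruning and cross-fitting the effects on non-endpoint
cohorts were all evaluated and do not remove it). On dense real panels
(millions of markers) the permutation null is much wider relative to
trait drift and the test behaves as intended. Interpret small Ghat
p-values on small populations as evidence of directional genetic change,
with the selection-versus-drift attribution resting on the magnitude.

## Selection scans

* **ROH.** PLINK-style scanning window: 50 SNPs per window, at most 1
  heterozygous and 5 missing calls for a window to be compliant; a SNP
  is in the homozygous state when the fraction of compliant windows
  covering it is at least 0.05. Maximal in-state runs are split at
  inter-SNP gaps > 1 Mb and kept if they have >= 65 SNPs, span >= 1 Mb
  and average at least 1 SNP per 50 kb. Hotspots are SNPs whose ROH
  occurrence (fraction of samples covered) reaches the top 0.5%
  (k-th-largest threshold with k = max(1, ceil(fraction*n)); ties are
  all included; all-zero occurrences yield no hotspots).
* **Windowed diversity and differentiation.** 50 kb windows advanced in
  10 kb steps (all outputs 0-based half-open). Per site,
  `pi = 2c(n-c)/(n(n-1))` from called allele counts; window pi divides
  the summed site values by the window length in bp (the VCFtools
  convention — this matters to the absolute values). FST uses the
  two-population Weir–Cockerham variance components as a ratio of sums
  over the window (Hudson's estimator available). The diversity
  contrast is `ln(pi_hi / pi_lo)`, undefined (and excluded from
  ranking) when either side is zero. The top 1% of windows by FST
  (upper tail) and by pi-ratio (both tails, 0.5% each, since loss of
  diversity in either group is informative) are flagged.
* **Contrast groups.** The high group takes the largest trait values
  among females born up to the second cohort; the low group the
  smallest values among females of the last cohort (45 per group by
  default); cohort differences are tested pairwise with Welch t-tests
  (Satterthwaite df).

## GWAS and pleiotropy profiling

The association model adds birth year and season as separate
fixed-effect factors to the same LMM machinery. Significance thresholds
are `0.05/N` (genome-wide, inclusive) and `1/N` (suggestive), with `N`
the number of LD-independent markers from greedy left-to-right pruning:
a variant is dropped when its r^2 with any retained variant among the
previous 50 retained markers on the chromosome exceeds 0.4
(pairwise-complete r^2 under missingness). The inflation factor is
`lambda = median(chi2(p)) / 0.4549`. Single-variant pleiotropy profiling
regresses each trait on the variant's dosage by OLS (with the same
factors) and reports per-genotype-class means and standard errors.

## Evidence intersection and enrichment

Flagged scan windows are merged into maximal regions; genome-wide
significant GWAS hits are padded by 25 kb and merged; the intersection
is the set of common regions. QTL-category enrichment counts, for each
category, database intervals touched by >= 1 bp of candidate; the
richness factor is that count over the category total. The bootstrap
null re-places the candidate set (same count, same length multiset)
uniformly on the genome per replicate, chromosome chosen proportional to
placeable span so no interval crosses a boundary; `p_boot` is the
plus-one exceedance fraction, BH-adjusted across categories. Region
re-placement (rather than QTL resampling) was chosen because it
preserves the candidate geometry that drives the overlap statistics.

## The simulator

The test bed is a forward-in-time closed nucleus herd:

* Founder genotypes Binomial(2, p), p ~ Beta(0.8, 0.8) per site;
  haplotypes by random phasing. 10 chromosomes of 5 Mb with 5000 SNPs
  at uniform positions; gametes receive one obligate plus
  Poisson(3) extra crossovers per chromosome, so the per-marker map
  distance emulates a dense genome-wide panel at desk scale.
* Nine birth-year cohorts (2009–2017 analogue) of 600 animals each, of
  which a random 110 per cohort are genotyped — herds are never fully
  genotyped, and equating herd and sample would understate Ne and
  overstate drift. Parents are truncation-selected on the polygenic
  index phenotype from the previous two cohorts (overlapping
  generations), subject to floors of 50 sires and 250 dams so
  truncation cannot collapse the effective population size (Ne ~ 170);
  `drift_only` replaces truncation by random choice with the same
  counts.
* The selected index has 20 QTL modelled as ongoing hard sweeps:
  founder MAF in [0.2, 0.45], the minor allele favoured, effect
  magnitudes 2.5–4 phenotypic units; h^2 = 0.8. Teat number has 60 QTL
  of small effect (|a| in [0.05, 0.35]) plus 3 antagonistic pleiotropic
  QTL shared with the index (teat effect 2.0 against the favoured
  allele), mirroring the three pleiotropic genome regions the emulated
  study design exhibits; liability (h^2 = 0.4) is rounded into integer
  teat counts in 10–18, the left count a binomial split of the total.
  Economic traits (LSW, LWW, D100, B100, L100 analogues) are linear in
  the pleiotropic dosages — D100/B100 with the teat trend, LSW/LWW/L100
  against it — plus Gaussian noise.
* Emitted fixtures are panel-ascertained: variants failing sample MAF
  >= 0.01 or exact-HWE p >= 1e-5 are dropped (with truth indices
  remapped), as a released SNP set would already be; phenotypes are
  assigned before ascertainment.

What the simulator does **not** emulate: sequence-level mutation,
genotyping or imputation error beyond the DR2/DP annotations it writes,
age structure within litters, maternal effects, and real LD/recombination
maps. Passing tests therefore demonstrate correctness and calibration of
the statistics under a faithful pedigree-drift-selection process, not
performance on any particular real panel.

## Quality control

Imputed-panel QC: DR2 >= 0.8 (when annotated), call rate >= 0.9, MAF >=
0.01, exact Hardy–Weinberg p >= 1e-5 (Wigginton enumeration, two-sided,
cached per allele-count configuration), and a mean-depth rule whose
direction is configurable (`retain_ge` 3, the conventional low-coverage
exclusion, is the default; `retain_lt` reproduces the literal protocol
line some pipelines print). Rules combine as AND; the report logs each
rule separately so either compound reading is auditable.

## Problem sizes and determinism

Default analyses run at ~1000 genotyped samples x ~4700 ascertained
markers; null-calibration checks use drift-only herds of ~800 samples
and 10–50 replicates; power checks use 8-cohort selection herds of 1000
over 10–20 replicates. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; a pipeline run is a pure function of
(inputs, config, seed) and reruns are hash-identical.
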
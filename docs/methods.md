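# Methods

This note documents the statistical models, numerical choices, and known
limitations of `hapgy`. Units are kg/ha for grain yield (GY), days for
days-to-heading (DH), cm for plant height (PH), and bp/Mb for physical
positions.

## Genotype representation and filters

Genotype calls are coded 0 (major homozygote), 2 (minor homozygote),
1 (heterozygote), −1 (missing). The panels this package targets are
advanced inbred lines with residual heterozygosity of a few percent, which
drives three conventions used throughout:

* **MAF** is an allele frequency: heterozygotes contribute half a minor
  dose. Default thresholds are ≤ 30% marker missingness and MAF ≥ 0.15 —
  the elevated MAF floor keeps every annual cohort of a pooled multi-year
  panel above ~0.05 after subsetting.
* **Line culling** (> 60% missing) runs after the marker filter, so line
  missingness is measured on the informative marker set.
* **No imputation** anywhere; a marker duplicated at the same (chromosome,
  position) keeps the copy with less missing data.

## Pairwise LD and the D′ confidence interval

Because lines are inbred, two-locus haplotypes are read directly from
homozygous calls (one gamete per line); heterozygous or missing calls drop
the line from that pair. No EM phasing is used — at < 2–3% heterozygosity
the information loss is negligible and the estimator stays deterministic.

For haplotype frequencies p_AB …, `D = p_AB − p_A p_B`,
`D′ = |D| / D_max`, `r² = D² / (p_A p_a p_B p_b)`. The 95% confidence
interval of |D′| follows the Gabriel/Haploview convention: the multinomial
likelihood of the four gamete counts is evaluated on a |D′| grid
(step 0.001) with allele frequencies fixed at their sample values, the
table oriented so the maximum-likelihood D is non-negative, the likelihood
normalized to sum to one, and the one-sided 5% and 95% cumulative points
reported. A grid step of 0.001 tracks a 0.0001-step oracle within ±0.002
(verified in the acceptance checks). Pair classes:

* strong LD: CI_low ≥ 0.6 and CI_high ≥ 0.95;
* strong recombination: CI_high < 0.90 (the classical Gabriel bound — the
  upstream description fixes only the strong-LD bounds, so the
  recombination bound is taken from the original method and is exposed as
  a parameter);
* inconclusive otherwise. The three rules partition the CI space.

**LD decay** pools intrachromosomal (distance, r²) pairs genome-wide,
subsamples to a configurable cap (default 50,000), and fits a
second-degree locally weighted regression (tricube weights, span 0.5,
evaluated on 512 log-spaced distances). statsmodels only ships a
degree-one lowess, so the local quadratic smoother is implemented
directly. The decay distance is the first baseline crossing (r² = 0.1),
linearly interpolated; it is undefined when the curve never crosses.

## Haplotype blocks

A candidate interval [a, b] of map-contiguous markers is a block when
(i) the outermost pair is in strong LD and (ii) at least 95% of its
informative pairwise comparisons (strong LD + strong recombination;
inconclusive pairs excluded from the denominator, switchable) are in
strong LD. Candidates are capped at a 10 Mb span (observed block spans in
GBS wheat panels are well under 1 Mb; the cap bounds compute), accepted
greedily by (SNP count desc, span desc, leftmost start), discarding
overlaps — Haploview-style and fully deterministic. Two-SNP blocks are
allowed (one informative pair).

Accepted blocks become multiallelic markers: a line's block allele is the
concatenated homozygous nucleotide string over member SNPs; a missing or
heterozygous member call makes the whole haplotype missing; alleles below
a 5% frequency floor are dropped from the catalogue and recoded missing.
Block ids are `HB<chrom>.<ordinal>` by start position within chromosome.

## Phenotype adjustment, ANOVA, heritability

Trials follow a resolvable alpha-lattice: experiments of 28 entries + 2
checks, 3 replicates, incomplete blocks within replicate.

* **GY** is adjusted for incomplete-block effects within replicate.
  Blocks are random: effects are estimated from residuals after removing
  replicate and entry means and shrunk by σ²_b / (σ²_b + σ²_e/n_b) with
  moment-based variance estimates — the balanced-design equivalent of the
  mixed-model BLUP, chosen over a full REML fit because it is exact where
  the design is balanced and transparent where it is not. A replicate with
  a single block contributes a zero block effect by construction.
* **DH and PH** use check-based adjustment
  `Y_adj = (Y_ij − Y_i) + Y_all` (trial check mean to grand check mean), a
  location shift that preserves within-trial entry ranking.
* **ANOVA / H²**: a two-way genotype × environment analysis from expected
  mean squares, with genotype and environment tested against the G×E
  stratum (mixed-model convention) and G×E against error:
  σ²_err = MS_err, σ²_GxE = (MS_GxE − MS_err)/r,
  σ²_G = (MS_G − MS_GxE)/(e·r), clamped at zero, and the entry-mean
  broad-sense heritability H² = σ²_G / (σ²_G + σ²_GxE/e + σ²_err/(e·r)).
  H² is computed per trial across environments. For unbalanced data the
  same formulas use the harmonic-mean replicate count per cell — a
  documented approximation in place of a two-crossed-random-effect REML,
  adequate for the mild unbalance that missing plots cause.

## Mixed-model association

Per trait × trial × environment the model is
`y = μ + PCs + (optional DH/PH) + block-allele dummies + u + e`,
`u ~ N(0, σ²_g K)`, `e ~ N(0, σ²_e I)`, with VanRaden method-1 kinship
(missing doses mean-imputed only for K). The variance ratio
δ = σ²_e/σ²_g is estimated once on the null (no-marker) model by profile
REML over log δ — a 33-point coarse grid on [−8, 8] refined by bounded
scalar minimization — through the spectral decomposition of K (the
EMMA/EMMAX formulation). Each block is then a GLS F-test of its k−1
treatment-coded dummies (reference = most frequent allele) in the whitened
regression; aliased columns drop out through the rank of the design.
Testing every block against a single null-model δ is the standard EMMAX
approximation; it keeps a 519-block × 28-trial-environment scan at
n ≈ 1,000 within seconds and is what the calibration checks validate
(λ ≈ 1 under a structured null). Allele classes with < 10 lines are
merged into missing; lines missing at a block are dropped from that
block's test with the whitening recomputed on the subset.

The PC count (0–10) minimizes the BIC of the fixed-effects-only
regression; ties resolve to fewer PCs.

**Allelic effects** are descriptive: the favorable allele maximizes the
adjusted-phenotype mean; additional alleles are also called favorable when
their mean exceeds the mean of all other lines by more than the standard
error of that difference (this operationalizes blocks with two favorable
alleles, for which no formal rule exists upstream); the effect in kg/ha is
mean(favorable carriers) − mean(all others).

## Stability rules

* Environment-specific: some EYT with p < 10⁻⁴ **and** ≥ 3 EYTs with
  p < 10⁻³ (the strong EYT counts toward the three), within one testing
  environment.
* Multi-environment: p < 10⁻³ hits covering ≥ 2 distinct environments and
  ≥ 2 distinct EYTs jointly (the stricter per-environment reading is a
  flag). A block may carry both labels.
* No multiple-testing correction beyond the fixed thresholds — the rules
  themselves are the replication filter. Under a complete uniform null
  (519 blocks × 7 EYTs × 4 environments) the expected number of false
  multi-env-stable blocks is ≈ 0.2 per dataset, which the tests verify as
  a mean below one.

## Epistasis scans

For a pair (triple) of blocks, a main-effects model with allele dummies is
compared against a model adding all interaction dummies (for triples: all
two-way terms in the reduced model, the three-way terms on top). The
reported p is the F-test of the added group and the variance share is the
partial R² = (RSS_reduced − RSS_full)/TSS — the *incremental* variance
beyond lower-order terms, which is the quantity a planted
interaction-only (XOR-like) architecture reproduces exactly. Interaction
cells with < 5 lines are pooled with the reference; allele classes with
< 10 lines merge into missing; complete cases per tuple. The phenotype is
the same adjusted GY used in the GWAS (plain linear regression; a
kinship-residualized option exists but is off by default). Genome-wide
pair scans are feasible (≈ 134k pairs at 519 blocks); three-way scans are
restricted to candidate triples built from marginal (p < 0.01) or
pairwise hits, capped at 10⁵ models.

## Stacking

The favorable-haplotype matrix codes 1 (primary favorable), 2 (secondary
favorable), 0 (other), −1 (missing). Stack counts are taken over
non-missing blocks only; lines called at fewer than a configurable
fraction of blocks (default off, 80% when enabled) are excluded from
count classes, since a missing call is evidence for neither presence nor
absence. The additive trend reports per-count-class mean GY, the percent
gain from the lowest to the highest populated class, and the OLS slope of
GY on count; with fewer than three populated classes the trend is
undefined. Frequency trajectories per EYT cohort flag blocks whose
favorable-allele frequency drops by more than a delta (default 0.10)
first-to-last with a negative rank trend. Observed-count grouping is used
throughout; no resampling of haplotype numbers is performed.

## Synthetic data generator

The generator is a forward-in-time founder-recombination model — chosen
over a coalescent because it directly mimics how a breeding program
produces inbred lines and block-structured LD:

* **Founders** (default 40) carry haplotypes with marginal MAF uniform on
  [0.2, 0.5] and ancestral LD from a Gaussian-copula AR(1) along each
  chromosome (correlation e^(−d/2 Mb)). Descendant haplotypes are mosaics
  of founder haplotypes; only ancestry is propagated and alleles are
  looked up at the end.
* **Crossing**: 8 generations of random mating with Poisson(1.5)
  crossovers per chromosome per meiosis (uniform positions), then 6
  selfing generations (residual heterozygosity ≈ (1/2)⁶ ≈ 1.6%, matching
  advanced inbreds). Missing calls injected at 10%.
* **Defaults**: 1,000 lines, three 100-Mb chromosomes, 2,001 markers —
  a desk-scale rendering of a multi-year elite-trial panel that
  reproduces its qualitative LD structure (r² ≈ 0.4 at < 0.5 Mb, decay to
  the 0.1 baseline at ~2 Mb) and, under the default thresholds, yields a
  block count in the ~500 range.
* **Phenotypes**: per environment, genetic value = additive QTL effects
  (kg/ha per minor-allele dose) + interaction terms (minor-homozygote
  product indicators) + a polygenic term N(0, σ²·K) (σ = 300 kg/ha),
  scaled per environment (G×E) and shifted by environment means
  (I 6,000 / MD 4,500 / SD 2,500 / HS 3,500 kg/ha, inside the observed
  range of such trials). Plot values add replicate (SD 100), incomplete
  block (SD 150), and residual noise; the residual SD is set analytically
  so the entry-mean H² = Var_g/(Var_g + σ²_plot/r) hits the target
  (defaults 0.60/0.50/0.40/0.35 for I/MD/SD/HS, inside the 0.31–0.63 range
  typical of these trials). DH is generated with a positive genetic
  correlation to GY under irrigation and negative under stress, mirroring
  the phenology-stress pattern of real panels.
* **Determinism**: one global seed expands into named per-stage
  substreams (SeedSequence.spawn), so adding a stage never perturbs
  earlier draws; all outputs are integer-RNG deterministic.

What the generator does **not** emulate: pedigree structure and selection
within the breeding program, allele-frequency change across cohorts
(cohorts are random slices), spatial field trends, linked selection, and
genotyping-error hets. Passing tests therefore demonstrate correctness of
the estimators under the stated generative model, not robustness to every
field artifact.

## Problem sizes in the checks

The automated checks run at the scale the estimators are designed for
while staying desk-sized by choice: 1,000 random ≤ 8-SNP chromosomes for
the block-finder oracle; 500 count tables for the CI oracle; six
replicates of a 519-block, n = 500 structured null for calibration; 100
phenotype replicates at n = 1,000 for effect/power and epistasis
recovery. The full simulated-cohort summary uses the generator defaults.

## Known limitations

* The EMMAX single-δ approximation slightly understates significance for
  markers with very large effects (where refitting δ per marker would
  matter); this is the standard trade-off for genome-wide scans.
* The unbalanced-ANOVA path is moment-based, not REML; severe unbalance
  (beyond missing plots) deserves a dedicated mixed-model fit.
* The block-adjustment shrinkage is exact only for balanced lattices.
* `dprime_ci` conditions on sample allele frequencies (as the Gabriel
  method does); frequency uncertainty is not propagated.
* Interchromosomal LD, four-gamete/solid-spine block definitions, and
  exhaustive three-locus scans are out of scope.
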
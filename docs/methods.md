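# Methods

This note documents the statistical models implemented in `microcohort`,
the defaults and why they were chosen, what the synthetic-cohort
generator does and does not emulate, and the numerical conventions used
in edge cases.

## Cohort statistics

Continuous variables are summarized as mean (SD) per group and compared
with the two-sample t test; the pooled-variance variant is the default
(matching the "independent samples t test" convention of mainstream
statistics packages), with Welch-Satterthwaite available by flag.
Whole-cohort columns are recombined exactly from per-group summaries:

    pooled variance = [Σ(nᵢ−1)sᵢ² + Σnᵢ(meanᵢ−M)²] / (Σnᵢ−1),

which equals the variance of the concatenated raw data. Note that
pooling two identical groups therefore shrinks the SD by
√(2(n−1)/(2n−1)) — a property of concatenation, not an error.

Categorical variables use Fisher's exact test for 2×2 tables and the
Pearson chi-square for r×c (the source analyses do not name their test;
both are exposed, and Yates continuity correction is applied to 2×2
tables only on request). Printed reports round means/SDs to 3
significant figures and p-values to 2 decimals.

BMI-for-age z-scores use the LMS method with L, M, S linearly
interpolated on age (months) within sex; z = ((BMI/M)^L − 1)/(L·S), or
ln(BMI/M)/S when L = 0. Weight classes are half-open with the boundary
going up: normal < 85th percentile ≤ overweight < 95th percentile ≤
obese, using the standard-normal quantiles 1.036433 and 1.644854. The
binary obesity flag merges normal and overweight into "non-obese".
No real growth reference is bundled (it is external data); tests use a
small synthetic LMS table and users may supply the WHO/CDC table as CSV
with columns `sex, age_months, L, M, S`.

## Digital-PCR copy number

Each chip partitions the reaction into `n` wells; with template
concentration λ copies/partition, a well is negative with probability
e^(−λ), so λ̂ = −ln(1 − positives/partitions). Saturated chips
(positives = partitions) are rejected rather than truncated. The AMY1
copy number is CNV = r·λ_AMY1/λ_RNaseP with the reference copy number
r = 2 (RNase P is a single-copy gene per haploid genome); r is exposed
as a parameter. Replicate wells are pooled by summing positives and
partitions before the Poisson correction. The low/high AMY1
dichotomization is a median split with ties assigned to "low" (the
source analysis does not state its cutoff; the median split is the
documented choice here).

## Alpha diversity

Counts are rarefied to a common depth by uniform subsampling without
replacement (multivariate hypergeometric); the default depth is the
minimum sample depth in the bundle, and samples below the requested
depth are dropped with a logged list. One seeded draw is taken by
default. Metrics are the plug-in estimators on the rarefied counts:
observed richness, Shannon in nats (base configurable), and Inverse
Simpson. Associations use OLS of the metric on the variable of interest
plus covariates, with the partial F test for the variable's block (equal
to t² for a single column) and a parametric two-sided p. When the pooled
two-ethnicity cohort is analyzed, ethnicity always enters as a
covariate; within-ethnicity strata never adjust for it.

## Beta diversity and PERMANOVA

Bray-Curtis and UniFrac distances are computed on rarefied tables
(scikit-bio backend). Weighted UniFrac uses the normalized variant so
distances stay in [0, 1]. PCoA eigendecomposes the double-centered
squared-distance matrix −½·J·D²·J; negative eigenvalues (non-Euclidean
inputs) are reported but excluded from coordinates and from the
proportion-explained denominator, and each axis's sign is fixed by
making its largest-magnitude coordinate positive so ordinations are
reproducible.

PERMANOVA follows the adonis convention: sequential (Type I) sums of
squares from traces of hat-projected Gower matrices, covariates entered
before the variable of interest; pseudo-F = (SS_var/df_var)/(SS_res/df_res).
Significance permutes the variable's rows while covariates stay fixed,
with p = (1 + #{F_perm ≥ F_obs})/(1 + B) so p is never 0. When the
variable admits fewer distinct row arrangements than B, all of them are
enumerated and p is the exact fraction with F ≥ F_obs (the observed
arrangement counts itself). If a design exhausts the distance sum of
squares (zero residual), pseudo-F is defined as +∞ so fully separated
toy configurations still order correctly under enumeration.

## Differential abundance

Per taxonomic rank, in order:

1. **Aggregate** ASV counts by the lineage prefix through the rank;
   ASVs unassigned at that rank pool into an `unclassified_<parent>`
   bucket under their last named ancestor. Aggregation conserves each
   sample's total count.
2. **Filter**: keep taxa present in strictly more than 10% of samples
   *and* with maximum per-sample relative abundance strictly above 0.2%.
3. **GMPR size factors** on the filtered table: r_ij is the median
   count ratio over taxa nonzero in both samples (at least `min_shared`
   shared taxa, default 1 since post-filter tables are dense); s_i is
   the geometric mean of r_ij over every j with a defined ratio,
   including the trivial self-ratio r_ii = 1 as in the method's
   reference formulation, then rescaled to geometric mean 1. Including
   the self-ratio makes the factors recover exact scalar multiples of a
   common composition exactly and keeps s_i/s_j ratio-equivariant under
   rescaling a sample. Factors are computed after the prevalence filter
   (the ordering is not stated in the source; "after" is the default and
   both are possible by calling the stages directly).
4. **Normalize and transform**: a_ik = count_ik/s_i, outcome √a_ik.
5. **Permutation F test** per taxon: the partial F statistic of the
   variable in OLS with covariates; the null is built by Freedman-Lane
   residual permutation (permute residuals of the covariate-only model,
   add back its fitted values, recompute F), which preserves covariate
   structure in the pooled, race-adjusted analysis. Simple label
   permutation is available by flag and coincides with Freedman-Lane
   when there are no covariates. B = 999 by default;
   p = (1 + #)/(1 + B). One shared permutation stream is used for all
   taxa of a rank (seeded per rank from the user seed), which keeps the
   full pipeline deterministic and invariant to row/column order
   (samples and taxa are canonically sorted internally).
6. **B-H FDR** within the rank: q_(i) = min_{j≥i} m·p_(j)/j, flagged at
   q < 0.10.

Constant outcomes are assigned F = 0, p = 1 rather than 0/0.

## Synthetic cohort generator

The generator's defaults are the study conditions: 30 children per
ethnicity; obese fraction 17/60; sex, household-income and
parental-education categories drawn per ethnicity from the published
cohort-table proportions; age ~ N(8.56, 1.41) years truncated to
[6, 10]; AMY1 CNV ~ N(7.11, 2.46) truncated positive; BMI z-scores drawn
from N(1.11, 1.23) truncated to the assigned obesity class so classes
and z-scores are mutually consistent; heights ~ N(134, 11.8) cm with
weights derived from BMI and height.

Counts are Dirichlet-multinomial: depth ~ LogNormal(ln 56,439, 0.5) —
the log-SD of 0.5 was chosen once so that a cohort of 60 depths spans
roughly the published 9,099–118,425 range around the published median —
with per-sample compositions Dirichlet(0.5 per taxon), a sparse
overdispersed default typical of 16S tables (no dispersion estimate
exists for the original cohort; this is plausible, not fitted). Spikes
multiply a taxon's concentration by 2^(lfc × covariate) with binary
covariates coded 0/1, so a spike of lfc on a rare taxon shifts its
expected relative abundance by ≈ 2^lfc between groups. dPCR wells draw
reference positives ~ Binomial(n, 1 − e^(−λ_ref)) with λ_ref = 0.5 and
target λ = λ_ref·CNV/2 from the participant's true CNV. Every artifact
draws from its own RNG substream keyed (seed, fixed offset), so adding
outputs never perturbs earlier ones and fixed seeds give byte-identical
outputs.

What the generator does **not** emulate: read-level error/chimera
structure, real SILVA lineages (the taxonomy is a random nested
hierarchy with ~5% unassigned genera), phylogenetic signal in
abundances (the random tree is independent of the compositions), and
between-taxon correlation beyond the Dirichlet's. Passing
recovery/calibration tests therefore demonstrates correctness of the
statistical machinery under the stated design, not robustness to every
feature of real 16S data.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to balance Monte-Carlo error
against runtime: type-I calibration uses B = 199 permutations with
rejection at p ≤ 0.05 (exactly nominal for the (1+#)/(1+B) estimator),
500–2,000 replicates or ≥ 500 null taxa; recovery checks use depth 10⁵
for GMPR, 100 chips of 20,000 partitions for dPCR, and 30 samples per
group with |lfc| = 3 for spike recovery. The analysis APIs keep the
full-scale defaults (B = 999, q < 0.10). Permutation F comparisons use
a 10⁻¹² tolerance when counting F_perm ≥ F_obs so exact ties (discrete
outcomes) count as exceedances, which keeps the test valid (slightly
conservative) for heavily tied data. Distance matrices are validated
symmetric with zero diagonal; Bray-Curtis is not a metric (triangle
inequality can fail) and no code path assumes it is.

## Known limitations

- GMPR is O(n²·m); fine for cohort-scale n, not for thousands of samples.
- The LMS interface interpolates linearly (not cubically) between
  reference rows; adequate at monthly resolution.
- PERMANOVA permutes the variable of interest only; exact restricted
  permutations for complex covariate designs are out of scope.
- The pipeline treats body sites independently; no paired gut/oral
  modeling.
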
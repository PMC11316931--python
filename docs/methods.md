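# Methods

This note documents the statistical models implemented in `hologuild`,
the defaults and conventions they use, what the synthetic cohort does and
does not emulate, and the numerical choices that make results exactly
reproducible.

## Study design being modelled

Two nested designs drive everything:

1. **Extreme-phenotype omics panel.** 18 animals — the 9 most and 9 least
   feed-efficient of a screened herd — with three omics layers measured in
   the rumen: metatranscriptome (MTT, count-valued), metaproteome (MTP)
   and metabolome (MTB, with spectral-library similarity scores and an
   origin classification per metabolite). The group label
   (`efficient` / `inefficient`) is an explicit sample annotation assigned
   by a median split of the feed-conversion-ratio (FCR) phenotype; lower
   FCR means more efficient. The pipeline never infers the label from the
   FCR sign convention.
2. **Genotyped cohort.** A larger cohort (hundreds to thousands of
   animals, tens of thousands of SNPs) carrying a heritable taxon
   abundance, used for the omics GWAS that feeds Mendelian randomization.

## Differential testing and functional groups

Per-feature two-group comparison uses the Wilcoxon rank-sum test: exact
enumeration whenever both groups have ≤ 10 samples and the pooled values
are tie-free, otherwise the tie-corrected normal approximation with
continuity correction. A feature constant across all samples gets p = 1
and a flag. Benjamini–Hochberg adjustment is applied across all features
of a layer. Fold change is log₂ of the ratio of group means (efficient
over inefficient) with a pseudo-count of half the smallest nonzero value
of the layer, so zero-mean groups stay finite; the log₂ scale is a package
convention. Significant features are cut into quartiles Q1–Q4 at the
empirical 25/50/75 percentiles of log₂ fold change, ties at a cut going to
the lower quartile (deterministic).

The three group builders apply conjunctive filter chains, so the
surviving set is independent of filter order:

* **MTT**: group-mean CPM > 5 in at least one group (CPM = per-sample
  rescaling to 10⁶), BH p < 0.05, up in efficient.
* **MTP**: quartiles Q3/Q4 of the significant set.
* **MTB**: prevalence strictly over 50 % of samples (zeros count as true
  absence, no pseudo-count), similarity strictly over 200, BH p < 0.05 and
  up in efficient, Spearman correlation with FCR at p < 0.05, origin in
  {microbiota, co-metabolism}. The origin classification is table-driven
  (a user- or generator-supplied lookup), which replaces an external
  metabolite-origin database query while preserving the decision logic.

All three thresholds are read strictly: CPM exactly 5, similarity exactly
200 and prevalence exactly 50 % are excluded. "Over 50 %" and "over 200"
are worded as strict in the protocols this mirrors; the comparators are
nonetheless configurable.

Enrichment uses the two-sided Fisher exact test of differential features
against all identified features of the layer, per functional vocabulary
(GO / KEGG / COG / protein domains), BH-adjusted within vocabulary. The
two-sided p sums hypergeometric probabilities no larger than the observed
table's; it is computed with exact integer arithmetic so ties at equal
probability are decided exactly rather than by floating-point rounding.
The quartile cluster matrix keeps categories with p < 0.05 in at least one
quartile, transforms x = −log₁₀(p), z-scores each category row with the
**population** SD (divide by n; zero-variance rows are set to 0 and
flagged), and clusters rows/columns by average linkage on Euclidean
distance.

## Community statistics

* Shannon uses the natural logarithm (recorded in output metadata).
* Chao1 is the classic estimator with the bias-corrected
  S_obs + F₁(F₁−1)/2 fallback when no doubletons exist; it requires
  integer counts.
* Bray–Curtis is computed on per-sample relative abundances; it is
  bounded in [0, 1] and symmetric but not a metric, so no triangle
  inequality is asserted or relied on.
* PERMANOVA decomposes sums of squared distances
  (SS_T = Σ_{i<j} d²ᵢⱼ / N, within-group analogues per group);
  pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)). Labels are permuted freely (no
  strata), the observed statistic is included in the permutation count
  (p ≥ 1/(n_perm+1)), and ≥ comparisons count ties. Note that pseudo-F
  depends on the induced partition only, so with g vs g samples the
  smallest attainable p is bounded below by the probability that a random
  permutation reproduces the partition (≈ 2/C(2g, g)); at 9 vs 9 this is
  ~4×10⁻⁵ and irrelevant, but at 3 vs 3 it is 0.1.
* PERMDISP embeds the distance matrix by principal coordinates, drops
  axes with eigenvalues ≤ 10⁻¹⁰·λ_max (the standard resolution of
  non-Euclidean Bray–Curtis embeddings), computes each sample's distance
  to its own group centroid, and permutes group labels of those distances
  under a one-way F.
* The effect size log₂(pseudo-F/q) uses q = BH-adjusted permutation p
  across the omics layers being compared, floored at 1/(n_perm+1). Reading
  the adjusted permutation p as "q" is an interpretation recorded here,
  not a claim about any external convention.
* When functional groups are compared, each group's member features are
  sliced from the **whole-community** relative-abundance table rather than
  renormalized within the subset; renormalizing would cancel any coherent
  shift shared by the group's members and erase exactly the signal being
  quantified.

## Mixed-model omics GWAS

Model: y = 1λ + a + g·x + e with a ~ N(0, G σ²_a), e ~ N(0, I σ²_e);
λ is the overall mean, x the variant coded −1/0/1 for AA/AB/BB, and
G = W Wᵀ / Σ 2pₖ(1−pₖ) the VanRaden genomic relationship on
column-centered codes (one record per animal, so the incidence matrix is
the identity).

QC defaults (package choices, configurable): MAF ≥ 0.05, missingness
≤ 0.10, exact conditional Hardy–Weinberg test p ≥ 10⁻⁶. The HWE test sums
probabilities of heterozygote counts no more probable than observed,
conditional on allele counts — robust at the small MAFs the filter
targets.

REML estimates (σ²_a, σ²_e) on the null model through a single spectral
decomposition of G and a bounded one-dimensional optimization of the
profiled restricted likelihood in h² ∈ [10⁻⁶, 1−10⁻⁶] (Brent,
xatol 10⁻⁸), guarded by a 21-point grid scan against local optima. The
components are then fixed and reused for every marker (P3D), so the scan
is a vectorized GLS with per-observation variances σ²_a λᵢ + σ²_e and a
normal Wald test; p-values are BH-adjusted across the scan. With G = I and
σ²_a = 0 the scan reduces exactly to per-marker OLS with known residual
variance (a regression test enforces this to 10⁻⁸ relative).

Missing genotypes are mean-imputed per variant both for the kinship and
for the per-marker tests; a single imputation rule keeps the rotated
design consistent across markers and is what the single shared spectral
decomposition requires. Markers constant after imputation are emitted with
p = 1 and a flag. A side effect of column centering worth knowing: the
expected off-diagonal of G for unrelated animals is ≈ −1/(n−1), not 0, so
"off-diagonals shrink to zero" only holds jointly in n and the number of
variants.

## Two-sample Mendelian randomization

Instrument selection takes variants below a significance threshold
(BH-adjusted p < 0.001 by default; the unadjusted-p convention used for
metabolite exposures is available via a flag) and greedily prunes by
ascending p so no retained pair has genotype r² > 0.1. Harmonization
aligns outcome effects to the exposure effect allele, sign-flipping
swapped codings and dropping strand-ambiguous A/T and C/G variants unless
allele frequencies on both sides are away from 0.5 and on the same side
(tolerance 0.08).

Estimators, for harmonized (β_x, β_y, σ_y) and Wald ratios β_y/β_x:

* **IVW**: β = Σ(β_x β_y/σ_y²)/Σ(β_x²/σ_y²), fixed-effect
  SE = (Σ β_x²/σ_y²)^(−1/2), inflated multiplicatively by √(Q/(k−1)) when
  Cochran Q exceeds its degrees of freedom.
* **MR-Egger**: weighted regression of β_y on β_x with a free intercept,
  weights 1/σ_y², instruments oriented so β_x ≥ 0; residual-scaled SEs and
  t-tests with k−2 df; the intercept estimates average directional
  pleiotropy. The intercept is an extrapolation to β_x = 0, so its power
  depends on the spread of instrument strengths, not only on k.
* **Weighted median**: ratios ordered; cumulative standardized weights
  sⱼ = (Σ_{k≤j} w_k − w_j/2)/Σw with w = β_x²/σ_y²; linear interpolation
  at s = 0.5. Consistent while invalid instruments carry < 50 % of weight.
* **Simple/weighted mode**: normal-kernel density over the ratios with
  bandwidth 0.9·min(SD, MAD_normal)·k^(−1/5) times a configurable factor
  (modified Silverman rule on the ratio dispersion); the estimate is the
  density argmax on a 1024-point grid; the weighted variant uses
  inverse-variance weights in the kernel sum.

Bootstrap SEs for median/mode are parametric (resample β_x, β_y from
their normals, 1000 draws by default) under a recorded seed. All
estimators are scale-equivariant: multiplying exposure effects by c
divides every causal estimate by c.

## Mediation

Two OLS fits, m = α₀ + a·x and y = β₀ + c′·x + b·m (optional shared
covariates in both), give ACME = a·b, ADE = c′ and the total effect from
y ~ x; in this linear no-interaction setting total = ACME + ADE holds as
an algebraic identity on the point estimates (asserted to 10⁻¹⁰).
Inference is a nonparametric case-resampling bootstrap — rows resampled
with replacement, both models refit, two-sided percentile p with the +1
convention so p ∈ [2/(B+1), 1] — rather than quasi-Bayesian coefficient
draws; resampling rows makes fewer distributional assumptions and is
deterministic under the recorded seed. The proportion mediated is
reported as undefined (with a warning) when |total| < 10⁻⁸. Covariates
default to none.

## The synthetic cohort

The generator is the package's definition of the study conditions:

* Genotypes: per-variant MAF ~ U(0.05, 0.5), allele counts
  Binomial(2, maf) centered to −1/0/1. Defaults: 298 animals, 20,571
  variants (the cohort scale of the emulated design).
* Causal chain (all Gaussian/log scale, matching the linear machinery
  downstream): taxon = Σ gₖαₖ + e with α ~ N(0,1) on 28 causal variants,
  rescaled after drawing so the realized genetic variance is exactly
  taxon_h2 (default 0.4, "moderately heritable"); mediator = θ·taxon +
  pleiotropy + N(0, σ²); phenotype = δ·mediator + γ·taxon + N(0, σ²).
  Defaults θ = δ = 0.5, γ = 0.2, σ = 0.7. True indirect effect θ·δ is
  recorded in the truth ledger. Optional pleiotropy gives a flagged
  fraction of causal variants a direct mediator effect, for exercising
  the Egger intercept and median/mode robustness.
* Omics panel: 18 samples, FCR ~ N(5.8, 0.25) vs N(7.0, 0.25), labels by
  median split. Feature log₂ abundances are Gaussian around per-feature
  baselines U(4, 14) with SD 0.7 (log-normal abundances — an assumption,
  chosen because proteomic/metabolomic intensities are commonly
  log-normal; the design does not state a family). 40 planted features
  per layer are shifted by ±2 log₂ units in the efficient group, half up
  and half down, mirroring a balanced up/down split. Planted features
  share a focused category signature so enrichment has a recoverable
  answer. MTT abundances are rounded to counts. Metabolite origins are
  drawn with the 50:4:114:117 microbiota/host/co-metabolism/other mix;
  similarity scores U(60, 340) straddle the 200 threshold; planted-up
  metabolites get microbiota/co-metabolism origin and similarity above
  200 so the full MTB filter chain is recoverable.

What the generator does **not** emulate: sequencing/spectral noise and
batch effects, compositional coupling between taxa, phylogenetic or LD
structure (variants are independent), library-size variation, missing
genotypes, or real taxonomic co-occurrence. Passing recovery tests
therefore demonstrates the statistical machinery is correct under the
stated model, not that the pipeline is robust to those real-data
artifacts.

A note on power at the default cohort scale: with heritability 0.4 spread
over 28 variants with N(0,1)-drawn effects, a ~300-animal GWAS detects
only the luckiest variants at BH-adjusted p < 0.001 — often none. This is
a property of the design, not a defect; simulations that need a full
instrument set (the MR recovery checks, the acceptance script) use a
larger simulated cohort (2000–4000 animals, 5000 variants, 30 causal
variants), where most instruments clear the threshold.

## Problem sizes used by the tests and acceptance script

Chosen to keep the default suite under a minute of compute while leaving
comfortable Monte-Carlo margins: PERMANOVA null calibration 1000
replicates × 999 permutations at n = 18; GWAS null calibration one scan
of 298 × 20,571 (cohort scale); planted-variant ranking 100 replicates on
a shared 1000 × 300 panel (5 % variance variant over a polygenic
background); REML recovery 50 replicates on a shared 2000-animal
relationship matrix; IVW coverage 500 replicates; robustness 200;
Egger type-I 1000; mediation recovery 200 replicates at n = 1000 and null
calibration 500 replicates (n = 200, 499 bootstrap draws); functional-group
recovery 100 replicates at 9 vs 9 with log₂ fold change 2. The
acceptance script runs the panel at its default size and the cohort at
4000 × 5000.

## Reproducibility

All randomness flows from integer seeds through `numpy` Generators;
per-operation child streams are derived as (seed, stream-index) seed
sequences, so stages are independently reproducible. TSV exports use a
fixed `%.10g` float format and JSON is written with sorted keys, making
repeated runs byte-identical (verified by manifest SHA-256 digests). A
resumed pipeline run reloads cached stage outputs at file precision, so
downstream results can differ from a cold run in the last digits.

## Known limitations

* The exact Wilcoxon path requires tie-free data; heavily tied layers fall
  back to the normal approximation even at n = 9 vs 9.
* PERMDISP tests dispersion given the PCoA embedding; axes dropped for
  negative eigenvalues discard a (usually tiny) part of the structure.
* The mode-based MR estimators inherit kernel-bandwidth sensitivity; the
  bandwidth factor is exposed but defaults to 1.
* Mediation assumes linear, no-interaction models and sequential
  ignorability; no sensitivity analysis is provided.
* The GWAS scan tests one variant at a time with fixed variance
  components (P3D); jointly modelling large-effect loci would require a
  re-estimated null per chromosome or leave-one-chromosome-out kinship,
  neither of which is implemented.
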
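# hologuild

Holo-omics functional-group construction and causal inference for the
rumen microbiome.

`hologuild` is for microbiome researchers who have layered omics data from
a two-group animal study — metatranscriptome (MTT), metaproteome (MTP) and
metabolome (MTB) feature tables from a small extreme-phenotype panel, plus
host SNP genotypes from a larger cohort — and want to go beyond
correlation: which microbial species carry the phenotype-associated
functions at each omics layer (the *functional groups*, or guilds), and
does a focal taxon **causally** drive the proteins/metabolites and, through
them, the phenotype (here: feed conversion ratio, FCR, in dairy cows)?

## What it computes

**Functional groups per omics layer.** Features are tested between the
efficient and inefficient groups (Wilcoxon rank-sum, Benjamini–Hochberg);
the layer-specific filter chains are:

* MTT: CPM > 5 (group mean), BH p < 0.05, up in efficient animals;
* MTP: differential proteins in the upper fold-change quartiles Q3/Q4;
* MTB: prevalence > 50 %, spectral similarity > 200, up in efficient
  animals, Spearman-correlated with FCR, and of microbiota or
  co-metabolism origin.

All thresholds are strict inequalities. Groups map feature → species →
family, export Sankey link tables, and are compared by species-set Venn
counts and Bray–Curtis PERMANOVA with the effect size
log₂(pseudo-F / q), where q is the BH-adjusted permutation p across layers.

**Community statistics.** Shannon H = −Σ pᵢ ln pᵢ, Chao1
S_obs + F₁²/(2F₂), Bray–Curtis dissimilarity, PCA, PERMANOVA
(pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)), R² = SS_A/SS_T, label-permutation
p) and PERMDISP.

**Omics GWAS.** Each omics feature is a quantitative trait under the
animal model y = 1λ + a + g·x + e with a ~ N(0, G σ²_a), G the VanRaden
genomic relationship, genotypes coded −1/0/1. Variance components are
estimated once by REML (P3D) and reused for every marker's GLS test.

**Two-sample Mendelian randomization.** Instruments selected at
BH-adjusted p < 0.001 and LD-pruned (r² ≤ 0.1); harmonized exposure/
outcome effects combined by IVW, MR-Egger (with the intercept as the
directional-pleiotropy test), weighted median, and simple/weighted mode,
plus Cochran Q heterogeneity.

**Mediation.** Linear decomposition of taxon → mediator → phenotype:
ACME = a·b, ADE = c′, total = ACME + ADE exactly, with case-resampling
bootstrap p-values.

**Synthetic cohort.** Because every stage is statistical, the package
ships a generator that emulates the study design — 18-sample 9 vs 9 omics
panel with planted differential features, and a genotyped cohort with a
heritable taxon, taxon-driven mediators, a mediator-driven phenotype and
optional pleiotropy — together with a ground-truth ledger, so recovery is
verifiable end to end.

## Worked example

Simulate a genotyped cohort (4000 animals, 5000 SNPs, 30 causal variants,
taxon h² = 0.4, θ = δ = 0.5, γ = 0.2), run the exposure GWAS in one half
and the outcome GWAS in the other, then MR and mediation:

```python
import numpy as np
import hologuild as hg
from hologuild.synthetic import CohortConfig

cfg = CohortConfig(n_animals=4000, n_variants=5000, n_causal_variants=30,
                   taxon_h2=0.4, seed=1)
genos = hg.simulate_genotypes(cfg)
taxon, mediator, phenotype, truth = hg.simulate_causal_chain(genos, cfg)

qc, report = hg.qc_variants(genos)
half = qc.n_animals // 2
summaries = {}
for name, trait, idx in [("taxon", taxon, np.arange(half)),
                         ("mediator", mediator, np.arange(half, qc.n_animals))]:
    sub = hg.GenotypeMatrix(qc.genotypes[idx], qc.variants.copy(),
                            [qc.sample_ids[i] for i in idx])
    fit = hg.fit_null_reml(trait.to_numpy()[idx], hg.kinship(sub))
    summaries[name] = hg.marker_scan(trait.to_numpy()[idx], sub, fit)
    print(f"{name}: REML h2 = {fit.h2:.3f}")

ivs = hg.select_instruments(summaries["taxon"], qc, p_adj_max=0.001)
h = hg.harmonize(summaries["taxon"][summaries["taxon"].variant_id.isin(ivs)],
                 summaries["mediator"][summaries["mediator"].variant_id.isin(ivs)])
estimates, q, q_df = hg.mr_report(h, n_boot=1000, seed=2)
for name, est in estimates.items():
    print(f"{name:>16}: beta = {est.beta:+.3f} (SE {est.se:.3f}, p = {est.p:.2g})")
med = hg.fit_mediation(taxon, mediator, phenotype, n_boot=1000, seed=3)
print(f"ACME = {med.acme:.3f}, ADE = {med.ade:.3f}, "
      f"prop. mediated = {med.prop_mediated:.2f}, p_ACME = {med.p_acme:.3g}")
```

Output:

```
taxon: REML h2 = 0.382
mediator: REML h2 = 0.135
             IVW: beta = +0.507 (SE 0.031, p = 2.3e-59)
           Egger: beta = +0.417 (SE 0.113, p = 0.0061)
 weighted_median: beta = +0.512 (SE 0.047, p = 2e-27)
     simple_mode: beta = +0.595 (SE 0.075, p = 2.4e-15)
   weighted_mode: beta = +0.546 (SE 0.066, p = 1.3e-16)
ACME = 0.264, ADE = 0.196, prop. mediated = 0.57, p_ACME = 0.002
```

The taxon's REML heritability estimate (0.382) recovers the simulated
h² = 0.4; all five MR estimators land near the true causal effect
θ = 0.5 of the taxon on the mediator; and the mediation decomposition
recovers the planted indirect effect θ·δ = 0.25 (ACME = 0.264) and direct
effect γ = 0.2 (ADE = 0.196), with total = ACME + ADE holding exactly.

The same chain runs from the shell:

```
hologuild run-all --config config.yaml --seed 1 --out-dir results/
```

with subcommands `simulate | diff | enrich | groups | community | gwas |
mr | mediate | run-all` for individual stages; every run writes a
manifest with SHA-256 digests of all outputs, and identical seeds produce
byte-identical files.

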
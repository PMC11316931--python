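"""Synthetic holo-omics cohort with a known causal ground truth.

The generator mirrors the statistical structure of a dairy-cattle
feed-efficiency study: a genotyped cohort (hundreds of animals, tens of
thousands of SNPs) carries a heritable rumen taxon abundance; the taxon
drives protein/metabolite mediators which in turn drive the
feed-conversion-ratio (FCR) phenotype; and a small 9 vs 9 extreme-group
design provides three omics feature tables (MTT transcripts, MTP proteins,
MTB metabolites) with planted differential features.  Every planted
quantity is recorded in a :class:`SyntheticTruth` ledger so downstream
stages have a recoverable answer.

Causal chain (all on the log/Gaussian scale the downstream linear
machinery assumes):

    taxon     = Σ_k g_k α_k + e_t          Var(genetic)/Var(total) = taxon_h2
    mediator  = θ·taxon + pleiotropy + e_m
    phenotype = δ·mediator + γ·taxon + e_p

so the true mediated (indirect) effect is exactly θ·δ.  Genetic effects α
are drawn N(0,1) on the causal variants and rescaled so the genetic
variance of the taxon hits ``taxon_h2`` exactly in the realized sample.
Optional pleiotropy gives a flagged fraction of causal variants a direct
effect on the mediator, which exercises the Egger-intercept and
weighted-median robustness checks downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas as gwas_mod
from .tables import (AnnotationMap, FeatureTable, write_annotations,
                     write_feature_table, write_phenotype)


class InvalidConfigError(ValueError):
    pass


# rumen-associated families and example species used to label synthetic features
_FAMILIES = (
    "Prevotellaceae", "Lachnospiraceae", "Ruminococcaceae", "Selenomonadaceae",
    "Clostridiaceae", "Succinivibrionaceae", "Fibrobacteraceae", "Veillonellaceae",
    "Eubacteriaceae", "Bacteroidaceae", "Spirochaetaceae", "Methanobacteriaceae",
)
_NAMED_SPECIES = (
    ("Selenomonas bovis", "Selenomonadaceae"),
    ("Selenomonas ruminantium", "Selenomonadaceae"),
    ("Prevotella bryantii", "Prevotellaceae"),
    ("Prevotella ruminicola", "Prevotellaceae"),
    ("Butyrivibrio fibrisolvens", "Lachnospiraceae"),
    ("Ruminococcus flavefaciens", "Ruminococcaceae"),
    ("Fibrobacter succinogenes", "Fibrobacteraceae"),
    ("Megasphaera elsdenii", "Veillonellaceae"),
)
_COG_LETTERS = "CEGIKLMOPT"
_ORIGINS = ("microbiota", "host", "co-metabolism", "others")
# origin mix for non-planted metabolites, matching the observed
# 50 / 4 / 114 / 117 split of microbial, host, co-metabolism, other peaks
_ORIGIN_PROBS = np.array([50, 4, 114, 117], dtype=float) / 285.0


@dataclass
class CohortConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults reproduce the cohort scale of the emulated design: 298
    genotyped animals, 20,571 SNPs, an 18-animal (9 vs 9) extreme-group
    omics panel, a moderately heritable taxon (h² = 0.4) and a planted
    log2 fold change of 2 for differential features.
    """

    n_animals: int = 298
    n_variants: int = 20571
    maf_range: tuple = (0.05, 0.5)
    n_causal_variants: int = 28
    taxon_h2: float = 0.4
    theta_taxon_to_mediator: float = 0.5
    delta_mediator_to_phenotype: float = 0.5
    gamma_direct: float = 0.2
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.1
    n_features_per_layer: tuple = (300, 250, 283)   # MTT, MTP, MTB
    n_differential: int = 40
    planted_log2fc: float = 2.0
    noise_sd: float = 0.7
    n_omics_samples: int = 18
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_animals < 2:
            raise InvalidConfigError("n_animals must be at least 2")
        if self.n_variants < 1 or self.n_causal_variants < 1:
            raise InvalidConfigError("variant counts must be positive")
        if self.n_causal_variants > self.n_variants:
            raise InvalidConfigError("n_causal_variants exceeds n_variants")
        if not 0 <= self.taxon_h2 < 1:
            raise InvalidConfigError("taxon_h2 must lie in [0, 1)")
        if not 0 <= self.pleiotropy_frac <= 1:
            raise InvalidConfigError("pleiotropy_frac must lie in [0, 1]")
        if any(n < 1 for n in self.n_features_per_layer):
            raise InvalidConfigError("feature counts must be positive")
        if self.n_differential > min(self.n_features_per_layer):
            raise InvalidConfigError("n_differential exceeds a layer's feature count")
        if self.n_omics_samples < 4 or self.n_omics_samples % 2:
            raise InvalidConfigError("n_omics_samples must be even and at least 4")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger: every planted id resolves in the emitted tables."""

    causal_variant_ids: list = field(default_factory=list)
    variant_effects: dict = field(default_factory=dict)       # id -> effect on taxon
    pleiotropic_variant_ids: list = field(default_factory=list)
    pleiotropy_effects: dict = field(default_factory=dict)    # id -> direct mediator effect
    theta: float = 0.0
    delta: float = 0.0
    gamma: float = 0.0
    acme: float = 0.0                                          # = theta * delta exactly
    differential_feature_ids: dict = field(default_factory=dict)  # layer -> {id: +1/-1}
    planted_species: dict = field(default_factory=dict)           # layer -> sorted species list
    mtb_qualifying_ids: list = field(default_factory=list)
    origin_labels: dict = field(default_factory=dict)
    similarity_scores: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: CohortConfig) -> gwas_mod.GenotypeMatrix:
    """Binomial(2, maf) genotypes centered to the −1/0/1 coding."""
    config.validate()
    rng = _rng(config, 1)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_variants)
    geno = rng.binomial(2, mafs[None, :], size=(config.n_animals, config.n_variants)) - 1.0
    realized = (geno.mean(axis=0) + 1.0) / 2.0
    variants = pd.DataFrame({
        "id": [f"snp{j:06d}" for j in range(config.n_variants)],
        "chrom": 1 + (np.arange(config.n_variants) % 29),
        "pos": 1000 + np.arange(config.n_variants) * 137,
        "a1": "A", "a2": "B",
        "maf": np.minimum(realized, 1.0 - realized),
    })
    sample_ids = [f"cow{i:04d}" for i in range(config.n_animals)]
    return gwas_mod.GenotypeMatrix(geno, variants, sample_ids)


# ---------------------------------------------------------------------------
# Causal chain
# ---------------------------------------------------------------------------

def simulate_causal_chain(genos: gwas_mod.GenotypeMatrix, config: CohortConfig):
    """Taxon, mediator and phenotype vectors plus the truth ledger.

    Genetic effects are rescaled after drawing so the realized genetic
    variance of the taxon equals ``taxon_h2`` (total variance 1).
    """
    config.validate()
    rng = _rng(config, 2)
    n, m = genos.n_animals, genos.n_variants
    causal_idx = np.sort(rng.choice(m, size=config.n_causal_variants, replace=False))
    alpha = rng.normal(0.0, 1.0, size=config.n_causal_variants)
    xc = genos.genotypes[:, causal_idx]
    xc = np.where(np.isnan(xc), np.nanmean(xc, axis=0, keepdims=True), xc)
    score = xc @ alpha
    sd = score.std()
    if config.taxon_h2 > 0 and sd > 0:
        alpha *= np.sqrt(config.taxon_h2) / sd
        score = xc @ alpha
    else:
        alpha[:] = 0.0
        score = np.zeros(n)
    resid_sd = np.sqrt(1.0 - config.taxon_h2)
    taxon = score + rng.normal(0.0, resid_sd, size=n)

    n_pleio = int(round(config.pleiotropy_frac * config.n_causal_variants))
    pleio_idx = causal_idx[rng.choice(config.n_causal_variants, size=n_pleio, replace=False)] \
        if n_pleio else np.array([], dtype=int)
    pleio_effects = rng.normal(config.pleiotropy_mean, abs(config.pleiotropy_mean) or 0.1,
                               size=n_pleio)
    pleio_term = np.zeros(n)
    if n_pleio:
        xp = genos.genotypes[:, pleio_idx]
        xp = np.where(np.isnan(xp), np.nanmean(xp, axis=0, keepdims=True), xp)
        pleio_term = xp @ pleio_effects

    theta = config.theta_taxon_to_mediator
    delta = config.delta_mediator_to_phenotype
    gamma = config.gamma_direct
    mediator = theta * taxon + pleio_term + rng.normal(0.0, config.noise_sd, size=n)
    phenotype = delta * mediator + gamma * taxon + rng.normal(0.0, config.noise_sd, size=n)

    ids = genos.variants["id"].to_numpy()
    truth = SyntheticTruth(
        causal_variant_ids=[str(ids[j]) for j in causal_idx],
        variant_effects={str(ids[j]): float(a) for j, a in zip(causal_idx, alpha)},
        pleiotropic_variant_ids=[str(ids[j]) for j in pleio_idx],
        pleiotropy_effects={str(ids[j]): float(e) for j, e in zip(pleio_idx, pleio_effects)},
        theta=theta, delta=delta, gamma=gamma, acme=theta * delta,
    )
    index = pd.Index(genos.sample_ids, name="sample")
    return (pd.Series(taxon, index=index, name="taxon"),
            pd.Series(mediator, index=index, name="mediator"),
            pd.Series(phenotype, index=index, name="phenotype"),
            truth)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _make_ontology(rng: np.random.Generator, n_species: int = 40):
    species = list(_NAMED_SPECIES)
    fam_cycle = list(_FAMILIES)
    k = 0
    while len(species) < n_species:
        fam = fam_cycle[k % len(fam_cycle)]
        genus = fam.replace("aceae", "a")
        species.append((f"{genus} sp. HG{k:03d}", fam))
        k += 1
    categories = ([f"COG:{c}" for c in _COG_LETTERS]
                  + [f"ko{10 + 10 * i:05d}" for i in range(12)]
                  + [f"GO:{6000 + 7 * i:07d}" for i in range(12)]
                  + [f"PF{100 + i:05d}" for i in range(10)])
    return species, categories


def simulate_feature_tables(config: CohortConfig):
    """Three 18-sample omics layers with planted differential features.

    Log2 abundances are Gaussian around a per-feature baseline (log-normal
    abundances); planted features are shifted by ``planted_log2fc`` in the
    efficient group, half upward and half downward, mirroring a balanced
    up/down split of differential features.  Metabolites carry origin
    labels (microbiota / host / co-metabolism / others) and spectral
    similarity scores straddling 200; planted-up metabolites are given
    microbiota or co-metabolism origin and similarity above 200 so the
    full MTB filter chain has a recoverable answer.

    Returns ``(tables, annotations, fcr, truth)`` with ``tables`` and
    ``annotations`` keyed by layer.
    """
    config.validate()
    rng = _rng(config, 3)
    n_samp = config.n_omics_samples
    half = n_samp // 2
    sample_ids = [f"cow{i:04d}" for i in range(n_samp)]
    # efficient animals convert feed better: lower FCR
    fcr_vals = np.concatenate([rng.normal(5.8, 0.25, size=half),
                               rng.normal(7.0, 0.25, size=half)])
    order = np.argsort(fcr_vals)
    groups = pd.Series("inefficient", index=sample_ids, name="group")
    groups.iloc[order[:half]] = "efficient"   # median split of the phenotype
    fcr = pd.Series(fcr_vals, index=sample_ids, name="fcr")
    eff_mask = (groups == "efficient").to_numpy()

    species, categories = _make_ontology(rng)
    tables: dict[str, FeatureTable] = {}
    annotations: dict[str, AnnotationMap] = {}
    truth = SyntheticTruth(theta=config.theta_taxon_to_mediator,
                           delta=config.delta_mediator_to_phenotype,
                           gamma=config.gamma_direct,
                           acme=config.theta_taxon_to_mediator
                           * config.delta_mediator_to_phenotype)

    for layer, n_feat in zip(("MTT", "MTP", "MTB"), config.n_features_per_layer):
        prefix = {"MTT": "tx", "MTP": "prot", "MTB": "met"}[layer]
        fids = [f"{prefix}{i:05d}" for i in range(n_feat)]
        base = rng.uniform(4.0, 14.0, size=n_feat)
        shift = np.zeros((n_feat, n_samp))
        planted = rng.choice(n_feat, size=config.n_differential, replace=False)
        signs = np.where(np.arange(config.n_differential) % 2 == 0, 1.0, -1.0)
        for idx, sgn in zip(planted, signs):
            shift[idx, eff_mask] = sgn * config.planted_log2fc
        log2ab = base[:, None] + shift + rng.normal(0.0, config.noise_sd,
                                                    size=(n_feat, n_samp))
        ab = np.power(2.0, log2ab)
        if layer == "MTT":
            ab = np.round(ab)   # transcript layer is count-valued
        df = pd.DataFrame(ab, index=pd.Index(fids, name="feature_id"), columns=sample_ids)
        tables[layer] = FeatureTable(layer, df, groups.copy())

        sp_idx = rng.integers(0, len(species), size=n_feat)
        tax = pd.DataFrame(
            {"species": [species[i][0] for i in sp_idx],
             "family": [species[i][1] for i in sp_idx]},
            index=pd.Index(fids, name="feature_id"))
        # planted features share a focused functional signature (carbohydrate
        # metabolism / chemotaxis style categories), the rest draw at random,
        # so enrichment has a recoverable answer
        focus = {1.0: categories[:3], -1.0: categories[3:6]}
        planted_sign = {int(idx): sgn for idx, sgn in zip(planted, signs)}
        cats = {}
        for i, fid in enumerate(fids):
            chosen = list(rng.choice(categories, size=rng.integers(1, 4), replace=False))
            if i in planted_sign:
                chosen.append(focus[planted_sign[i]][rng.integers(0, 3)])
            cats[fid] = frozenset(chosen)
        met_info = None
        if layer == "MTB":
            origin = rng.choice(_ORIGINS, size=n_feat, p=_ORIGIN_PROBS)
            similarity = rng.uniform(60.0, 340.0, size=n_feat)
            for k, (idx, sgn) in enumerate(zip(planted, signs)):
                if sgn > 0:   # planted-up metabolites pass the origin/similarity filters
                    origin[idx] = "microbiota" if k % 4 else "co-metabolism"
                    similarity[idx] = rng.uniform(220.0, 340.0)
            met_info = pd.DataFrame({"origin": origin, "similarity": similarity},
                                    index=pd.Index(fids, name="feature_id"))
            truth.origin_labels = dict(zip(fids, origin))
            truth.similarity_scores = {f: float(s) for f, s in zip(fids, similarity)}
            truth.mtb_qualifying_ids = sorted(
                fids[idx] for idx, sgn in zip(planted, signs) if sgn > 0)
        annotations[layer] = AnnotationMap(tax, cats, met_info)

        truth.differential_feature_ids[layer] = {
            fids[idx]: int(sgn) for idx, sgn in zip(planted, signs)}
        truth.planted_species[layer] = sorted(
            {tax.loc[fids[idx], "species"] for idx, sgn in zip(planted, signs) if sgn > 0})

    return tables, annotations, fcr, truth


# ---------------------------------------------------------------------------
# Full-cohort convenience and export
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig):
    """Genotypes + causal chain + omics tables in one call.

    The two truth ledgers (causal chain, planted features) are merged.
    """
    genos = simulate_genotypes(config)
    taxon, mediator, phenotype, truth = simulate_causal_chain(genos, config)
    tables, annotations, fcr, feat_truth = simulate_feature_tables(config)
    truth.differential_feature_ids = feat_truth.differential_feature_ids
    truth.planted_species = feat_truth.planted_species
    truth.mtb_qualifying_ids = feat_truth.mtb_qualifying_ids
    truth.origin_labels = feat_truth.origin_labels
    truth.similarity_scores = feat_truth.similarity_scores
    return {"genotypes": genos, "taxon": taxon, "mediator": mediator,
            "phenotype": phenotype, "tables": tables, "annotations": annotations,
            "fcr": fcr, "truth": truth}


def write_cohort(cohort: dict, out_dir, vcf: bool = False) -> list:
    """Export the cohort as plain-text files; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    genos = cohort["genotypes"]
    gwas_mod.write_plink(genos, str(out / "genotypes"))
    written += [out / "genotypes.ped", out / "genotypes.map"]
    if vcf:
        gwas_mod.write_vcf(genos, str(out / "genotypes.vcf"))
        written.append(out / "genotypes.vcf")
    chain = pd.DataFrame({"sample": cohort["taxon"].index,
                          "taxon": cohort["taxon"].values,
                          "mediator": cohort["mediator"].values,
                          "phenotype": cohort["phenotype"].values})
    chain.to_csv(out / "causal_chain.tsv", sep="\t", index=False, float_format="%.10g")
    written.append(out / "causal_chain.tsv")
    for layer, table in cohort["tables"].items():
        write_feature_table(table, out / f"{layer.lower()}_abundance.tsv")
        write_annotations(cohort["annotations"][layer], out / f"{layer.lower()}_annotations.tsv")
        written += [out / f"{layer.lower()}_abundance.tsv",
                    out / f"{layer.lower()}_annotations.tsv"]
    write_phenotype(cohort["fcr"], cohort["tables"]["MTT"].groups, out / "phenotype.tsv")
    written.append(out / "phenotype.tsv")
    cohort["truth"].to_json(out / "truth.json")
    written.append(out / "truth.json")
    return [str(p) for p in written]
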
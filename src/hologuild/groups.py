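"""Construction and comparison of omics-layer functional groups (guilds).

A functional group is the set of microbial species carrying
feed-efficiency-associated functions at one omics layer:

* MTT group — features with CPM > 5 (group mean in at least one group),
  BH-adjusted rank-sum p < 0.05, and higher in the efficient animals.
* MTP group — differentially expressed proteins falling in fold-change
  quartiles Q3/Q4 (the quartiles up in efficient animals).
* MTB group — metabolites passing the full filter chain: detected in over
  half the samples, spectral-library similarity over 200, significantly
  higher in efficient animals, Spearman-correlated with the feed
  conversion ratio, and of microbiota or co-metabolism origin.

All threshold comparisons are strict inequalities (CPM exactly 5,
similarity exactly 200 and prevalence exactly 50% are excluded).  Groups
map features → species → family, keep per-link provenance, and are
compared by species-set Venn counts and per-layer Bray–Curtis PERMANOVA
with the log2(pseudo-F/q) effect size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import community
from .differential import bh_adjust, wilcoxon_bh
from .tables import AnnotationMap, FeatureTable, normalize_cpm

logger = logging.getLogger("hologuild")

MTB_ORIGINS = ("microbiota", "co-metabolism")


@dataclass
class FunctionalGroup:
    layer: str
    members: set  # of (species, family)
    function_links: set  # of (species, category)
    provenance: dict = field(default_factory=dict)  # feature_id -> {species, family, categories}

    @property
    def species(self) -> set:
        return {s for s, _ in self.members}

    def __len__(self) -> int:
        return len(self.members)


def _assemble(layer: str, feature_ids, annotations: AnnotationMap) -> FunctionalGroup:
    members, links, prov = set(), set(), {}
    for fid in feature_ids:
        tax = annotations.species_of(fid)
        if tax is None:
            logger.info("groups: feature %s lacks taxonomy, skipped", fid)
            continue
        species, family = tax
        cats = annotations.categories_of(fid)
        members.add((species, family))
        for cat in cats:
            links.add((species, cat))
        prov[fid] = {"species": species, "family": family, "categories": sorted(cats)}
    if not members:
        logger.warning("groups: empty %s functional group", layer)
    return FunctionalGroup(layer, members, links, prov)


def build_mtt_group(table: FeatureTable, annotations: AnnotationMap,
                    alpha: float = 0.05, cpm_min: float = 5.0,
                    diff: pd.DataFrame | None = None) -> FunctionalGroup:
    """Transcript-based group: CPM > 5, BH p < alpha, up in efficient.

    The CPM filter requires the group-mean CPM to exceed ``cpm_min``
    (strict) in at least one of the two groups.  Differential results may
    be supplied; otherwise the rank-sum scan runs on the CPM table.
    """
    cpm = normalize_cpm(table)
    if diff is None:
        diff = wilcoxon_bh(cpm, alpha=alpha)
    eff = cpm.samples_in("efficient")
    ineff = cpm.samples_in("inefficient")
    mean_eff = cpm.abundance[eff].mean(axis=1)
    mean_ineff = cpm.abundance[ineff].mean(axis=1)
    expressed = (mean_eff > cpm_min) | (mean_ineff > cpm_min)
    keep = diff.index[(diff["p_adj"] < alpha) & (diff["direction"] == "up")
                      & expressed.reindex(diff.index).fillna(False)]
    return _assemble("MTT", keep, annotations)


def build_mtp_group(table: FeatureTable, annotations: AnnotationMap,
                    diff: pd.DataFrame, quartiles: tuple = ("Q3", "Q4")) -> FunctionalGroup:
    """Protein-based group: DEPs in the upper fold-change quartiles Q3/Q4."""
    if "quartile" not in diff.columns or diff["quartile"].isna().all():
        raise ValueError("quartile labels missing; run fold_change_quartiles first")
    keep = diff.index[diff["quartile"].isin(quartiles)]
    return _assemble("MTP", keep, annotations)


def build_mtb_group(table: FeatureTable, annotations: AnnotationMap,
                    fcr: pd.Series, alpha: float = 0.05,
                    similarity_min: float = 200.0, prevalence_min: float = 0.5,
                    corr_alpha: float = 0.05,
                    diff: pd.DataFrame | None = None) -> FunctionalGroup:
    """Metabolite-based group via the four-filter chain plus origin rule.

    Filters (order-invariant): prevalence strictly over ``prevalence_min``;
    similarity strictly over ``similarity_min``; significantly higher in
    efficient animals (BH p < alpha); Spearman correlation with FCR at
    p < ``corr_alpha``; origin in {microbiota, co-metabolism}.  Metabolites
    without an origin annotation are skipped with a log entry.
    """
    info = annotations.metabolite_info
    if info is None:
        raise ValueError("metabolite origin/similarity annotations required")
    if diff is None:
        diff = wilcoxon_bh(table, alpha=alpha)
    ab = table.abundance
    prevalence = (ab > 0).mean(axis=1)
    fcr = fcr.reindex(table.sample_ids)

    keep = []
    for fid in ab.index:
        if fid not in info.index or pd.isna(info.loc[fid, "origin"]):
            logger.info("groups: metabolite %s lacks origin annotation, skipped", fid)
            continue
        if info.loc[fid, "origin"] not in MTB_ORIGINS:
            continue
        if not prevalence[fid] > prevalence_min:
            continue
        if not float(info.loc[fid, "similarity"]) > similarity_min:
            continue
        if not (diff.loc[fid, "p_adj"] < alpha and diff.loc[fid, "direction"] == "up"):
            continue
        rho, p = stats.spearmanr(ab.loc[fid].to_numpy(dtype=float), fcr.to_numpy(dtype=float))
        if not p < corr_alpha:
            continue
        keep.append(fid)
    return _assemble("MTB", keep, annotations)


def compare_groups(groups: dict[str, FunctionalGroup],
                   tables: dict[str, FeatureTable],
                   n_perm: int = 999, seed=None):
    """Venn species counts and per-layer PERMANOVA of group submatrices.

    For each layer, the features that produced the group (provenance) are
    sliced from the layer table, Bray–Curtis distances are computed on
    relative abundances, and PERMANOVA against the efficiency grouping is
    run; permutation p-values are BH-adjusted across the layers to give q
    and log2(pseudo-F/q).
    """
    sets = {layer: g.species for layer, g in groups.items()}
    layers = list(sets)
    venn = {}
    for layer in layers:
        venn[layer] = len(sets[layer])
    for i, a in enumerate(layers):
        for b in layers[i + 1:]:
            venn[f"{a}&{b}"] = len(sets[a] & sets[b])
    if len(layers) == 3:
        venn["&".join(layers)] = len(sets[layers[0]] & sets[layers[1]] & sets[layers[2]])
    for layer in layers:
        others = [sets[o] for o in layers if o != layer]
        venn[f"{layer}_unique"] = len(sets[layer].difference(*others)) if others else len(sets[layer])

    perma: dict[str, community.PermanovaResult] = {}
    rng = np.random.default_rng(seed)
    for layer, g in groups.items():
        table = tables[layer]
        fids = [f for f in g.provenance if f in table.abundance.index]
        if len(fids) < 1:
            logger.warning("groups: no features to compare for %s", layer)
            continue
        # relative abundance within the whole community, then subset, so a
        # coherent shift of the group's members is not normalized away
        rel_full = table.abundance.div(table.abundance.sum(axis=0), axis=1)
        rel = rel_full.loc[fids].T  # samples × features
        dist = community.bray_curtis(rel)
        perma[layer] = community.permanova(dist, table.groups, n_perm=n_perm,
                                           seed=rng.integers(2**31 - 1))
    if perma:
        qs = bh_adjust(np.array([r.p_perm for r in perma.values()]))
        for r, q in zip(perma.values(), qs):
            r.with_q(float(q))
    return venn, perma


def export_sankey(group: FunctionalGroup) -> pd.DataFrame:
    """Three-level link table (category → species → family) with weights.

    Link weight is the number of supporting features, so the weights out of
    a species across its family link equal its supporting-feature count.
    """
    rows = []
    counts: dict[tuple, int] = {}
    for fid, info in group.provenance.items():
        sp, fam = info["species"], info["family"]
        counts[("species-family", sp, fam)] = counts.get(("species-family", sp, fam), 0) + 1
        for cat in info["categories"]:
            counts[("category-species", cat, sp)] = counts.get(("category-species", cat, sp), 0) + 1
    for (level, src, dst), w in sorted(counts.items()):
        rows.append({"source": src, "target": dst, "level": level, "weight": w})
    return pd.DataFrame(rows, columns=["source", "target", "level", "weight"])


def write_group(group: FunctionalGroup, path) -> None:
    rows = [{"feature_id": fid, **{k: (";".join(v) if isinstance(v, list) else v)
                                   for k, v in info.items()}}
            for fid, info in sorted(group.provenance.items())]
    pd.DataFrame(rows, columns=["feature_id", "species", "family", "categories"]).to_csv(
        path, sep="\t", index=False)
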
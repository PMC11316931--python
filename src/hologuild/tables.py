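"""Feature tables, annotations, and phenotypes for the three omics layers.

A :class:`FeatureTable` holds one omics layer — ruminal metatranscriptome
(MTT), metaproteome (MTP), or metabolome (MTB) — as a features × samples
abundance matrix plus a per-sample feed-efficiency group label
(``efficient`` / ``inefficient``).  All downstream stages (differential
testing, enrichment, functional-group construction, community statistics)
consume this container, so validation is strict: ids must be unique,
abundances finite and non-negative, and every sample labelled.

The on-disk dialect is plain TSV, UTF-8, first column header
``feature_id``, remaining columns sample ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hologuild")

LAYERS = ("MTT", "MTP", "MTB")
GROUPS = ("efficient", "inefficient")
ORIGIN_CLASSES = ("microbiota", "host", "co-metabolism", "others")


class FormatError(ValueError):
    """Raised when an input file violates the table contract."""


class DegenerateSampleError(ValueError):
    """Raised when a sample is unusable (e.g. zero column sum for CPM)."""


@dataclass
class FeatureTable:
    """One omics layer: features × samples abundances plus group labels.

    Parameters
    ----------
    layer : str
        One of ``MTT``, ``MTP``, ``MTB``.
    abundance : pandas.DataFrame
        Features in rows (index = feature ids), samples in columns.
    groups : pandas.Series
        Sample id → group label (``efficient`` or ``inefficient``).
    """

    layer: str
    abundance: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        ab = self.abundance
        if ab.index.duplicated().any():
            dup = ab.index[ab.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dup[:5]}")
        if ab.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        vals = ab.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError("abundance matrix contains non-finite or missing values")
        if (vals < 0).any():
            raise FormatError("abundance matrix contains negative values")
        if not all(dt.kind == "f" for dt in ab.dtypes):
            self.abundance = ab.astype(float)
        self.groups = self.groups.reindex(ab.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise FormatError(f"samples without group label: {missing[:5]}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")

    # -- convenience -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_features(self, ids) -> "FeatureTable":
        ids = [i for i in ids if i in self.abundance.index]
        return FeatureTable(self.layer, self.abundance.loc[ids], self.groups.copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.layer, self.abundance.copy(), self.groups.copy())


@dataclass
class AnnotationMap:
    """Feature annotations shared by enrichment and group construction.

    ``taxonomy`` maps feature_id → (species, family); ``categories`` maps
    feature_id → set of functional category ids (COG letters, GO/KEGG ids,
    protein-domain ids); ``metabolite_info`` maps metabolite_id →
    (origin label, similarity score) where the origin label is one of
    ``microbiota``, ``host``, ``co-metabolism``, ``others``.
    """

    taxonomy: pd.DataFrame  # index feature_id; columns species, family
    categories: dict[str, frozenset] = field(default_factory=dict)
    metabolite_info: pd.DataFrame | None = None  # index metabolite_id; columns origin, similarity

    def __post_init__(self) -> None:
        need = {"species", "family"}
        if not need.issubset(self.taxonomy.columns):
            raise FormatError("taxonomy requires species and family columns")
        if self.metabolite_info is not None:
            bad = set(self.metabolite_info["origin"].dropna().unique()) - set(ORIGIN_CLASSES)
            if bad:
                raise FormatError(f"unknown metabolite origin labels: {sorted(bad)}")

    def species_of(self, feature_id: str) -> tuple[str, str] | None:
        if feature_id in self.taxonomy.index:
            row = self.taxonomy.loc[feature_id]
            return str(row["species"]), str(row["family"])
        return None

    def categories_of(self, feature_id: str) -> frozenset:
        return self.categories.get(feature_id, frozenset())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, layer: str, groups: pd.Series | None = None,
                       phenotype_path=None) -> FeatureTable:
    """Read a TSV feature table (first column ``feature_id``).

    Group labels come either from ``groups`` or from a phenotype TSV with
    columns ``sample``, ``fcr``, ``group``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "feature_id":
        raise FormatError(f"first column must be 'feature_id', got {df.columns[0]!r}")
    df = df.set_index("feature_id")
    if df.isna().any().any():
        raise FormatError(f"missing cells in {path}")
    if groups is None:
        if phenotype_path is None:
            raise ValueError("either groups or phenotype_path is required")
        groups = read_phenotype(phenotype_path)["group"]
    return FeatureTable(layer, df.astype(float), groups)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.abundance.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_phenotype(path) -> pd.DataFrame:
    """Phenotype TSV with columns sample, fcr, group → DataFrame indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "fcr", "group"):
        if col not in df.columns:
            raise FormatError(f"phenotype table lacks column {col!r}")
    return df.set_index("sample")


def write_phenotype(fcr: pd.Series, groups: pd.Series, path) -> None:
    df = pd.DataFrame({"sample": fcr.index, "fcr": fcr.values,
                       "group": groups.reindex(fcr.index).values})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotations(taxonomy_path, categories_path=None, metabolite_path=None) -> AnnotationMap:
    """Read annotation sidecars.

    ``taxonomy_path``: TSV feature_id, species, family (optionally
    ``categories`` semicolon-joined, ``origin``, ``similarity`` in the same
    file).  Separate category / metabolite sidecars override inline columns.
    """
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str).set_index("feature_id")
    categories: dict[str, frozenset] = {}
    if "categories" in tax.columns:
        for fid, cell in tax["categories"].dropna().items():
            cats = frozenset(c for c in str(cell).split(";") if c)
            if cats:
                categories[fid] = cats
    met = None
    if {"origin", "similarity"}.issubset(tax.columns):
        sub = tax.dropna(subset=["origin"])
        if len(sub):
            met = pd.DataFrame({"origin": sub["origin"],
                                "similarity": sub["similarity"].astype(float)})
    if categories_path is not None:
        cdf = pd.read_csv(categories_path, sep="\t", dtype=str)
        categories = {}
        for fid, cell in zip(cdf["feature_id"], cdf["categories"]):
            categories[fid] = frozenset(c for c in str(cell).split(";") if c)
    if metabolite_path is not None:
        mdf = pd.read_csv(metabolite_path, sep="\t", dtype={"feature_id": str}).set_index("feature_id")
        met = pd.DataFrame({"origin": mdf["origin"],
                            "similarity": mdf["similarity"].astype(float)})
    return AnnotationMap(tax[["species", "family"]], categories, met)


def write_annotations(ann: AnnotationMap, path) -> None:
    df = ann.taxonomy.copy()
    df["categories"] = [";".join(sorted(ann.categories.get(f, ()))) for f in df.index]
    if ann.metabolite_info is not None:
        df["origin"] = ann.metabolite_info["origin"].reindex(df.index)
        df["similarity"] = ann.metabolite_info["similarity"].reindex(df.index)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------

def normalize_cpm(table: FeatureTable) -> FeatureTable:
    """Rescale every sample (column) to sum to one million.

    Counts-per-million is the scale presumed by the CPM > 5 expression
    filter in MTT group construction.  Idempotent; within-sample
    proportions are preserved exactly.
    """
    sums = table.abundance.sum(axis=0)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise DegenerateSampleError(f"zero column sum for samples: {zero}")
    out = table.abundance.div(sums, axis=1) * 1e6
    return FeatureTable(table.layer, out, table.groups.copy())


def filter_prevalence(table: FeatureTable, min_frac: float, strict: bool = True) -> FeatureTable:
    """Keep features detected in more than ``min_frac`` of samples.

    "Over 50% of the samples" is read as a strict inequality: a feature
    present in exactly half the samples is removed at ``min_frac=0.5``.
    Zeros count as true absence; no pseudo-count is applied here.
    """
    if not 0 <= min_frac <= 1:
        raise ValueError("min_frac must be in [0, 1]")
    frac = (table.abundance > 0).mean(axis=1)
    keep = frac > min_frac if strict else frac >= min_frac
    return FeatureTable(table.layer, table.abundance.loc[keep], table.groups.copy())
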
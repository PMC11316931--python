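"""Fisher-exact functional enrichment and quartile-wise cluster matrices.

Differential features are tested for over-representation of functional
categories (GO terms, KEGG pathways, COG letters, protein domains) against
the background of all identified features of the layer, one two-sided
Fisher exact test per category, BH-adjusted within each vocabulary.

The quartile clustering matrix retains categories enriched (p below a
threshold) in at least one fold-change quartile, transforms p to
x = −log10(p), z-scores each category row (population SD so degenerate
rows are exactly reproducible), and clusters rows and columns by average
linkage on Euclidean distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list, to_tree
from scipy.spatial.distance import pdist

from .differential import bh_adjust
from .tables import AnnotationMap

logger = logging.getLogger("hologuild")

VOCABULARIES = ("GO", "KEGG", "COG", "domain")


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2×2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities ≤ the observed table's probability at
    fixed margins.  Implemented with exact integer arithmetic so ties are
    decided exactly, never by floating-point rounding.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("negative cell count")
    n = a + b + c + d
    r1 = a + b      # DE features
    c1 = a + c      # features in category
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table possible / no contrast
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    # unnormalized integer weights C(r1,k) C(n-r1, c1-k)
    weights = [comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    obs = weights[a - lo]
    total = sum(weights)
    tail = sum(w for w in weights if w <= obs)
    return tail / total


@dataclass
class EnrichmentResult:
    category_id: str
    vocabulary: str
    a: int  # DE in category
    b: int  # DE not in category
    c: int  # background (non-DE) in category
    d: int  # background (non-DE) not in category
    p: float
    p_adj: float = float("nan")
    odds_ratio: float = float("nan")


def fisher_enrichment(de_ids, background_ids, annotations: AnnotationMap,
                      vocabulary: str, category_filter=None) -> list[EnrichmentResult]:
    """Per-category Fisher enrichment of DE features against the background.

    ``background_ids`` is the full set of identified features (a superset of
    ``de_ids``); the non-DE part of the background forms the comparison
    margin.  BH adjustment is applied within the vocabulary.
    """
    de = set(de_ids)
    bg = set(background_ids)
    if not bg:
        raise ValueError("empty background")
    if not de <= bg:
        raise ValueError("de_ids must be a subset of background_ids")
    if vocabulary not in VOCABULARIES:
        raise ValueError(f"unknown vocabulary {vocabulary!r}")

    cat_members: dict[str, set] = {}
    for fid in bg:
        for cat in annotations.categories_of(fid):
            if category_filter is not None and not category_filter(cat):
                continue
            cat_members.setdefault(cat, set()).add(fid)
    results = []
    n_de = len(de)
    n_bg_other = len(bg) - n_de
    for cat, members in sorted(cat_members.items()):
        if not members:
            logger.info("enrichment: category %s absent from background, skipped", cat)
            continue
        a = len(members & de)
        b = n_de - a
        c = len(members) - a
        d = n_bg_other - c
        p = fisher_two_sided(a, b, c, d)
        orr = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
        results.append(EnrichmentResult(cat, vocabulary, a, b, c, d, p, odds_ratio=orr))
    if results:
        padj = bh_adjust(np.array([r.p for r in results]))
        for r, q in zip(results, padj):
            r.p_adj = float(q)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if len(df):
        df = df.set_index("category_id")
    return df


def quartile_cluster_matrix(enrichments_per_quartile: dict[str, list[EnrichmentResult]],
                            p_threshold: float = 0.05):
    """Build the z-scored −log10(p) matrix across fold-change quartiles.

    Categories enriched with p < ``p_threshold`` in at least one quartile
    are retained; x = −log10(p) rows are z-scored with the population SD.
    Zero-variance rows are set to 0 and flagged.  Returns
    (z DataFrame, row leaf order, column leaf order, row linkage, col linkage).
    """
    cols = list(enrichments_per_quartile)
    if len(cols) < 2:
        raise ValueError("need at least two quartile columns")
    pmat: dict[str, dict[str, float]] = {}
    for q, results in enrichments_per_quartile.items():
        for r in results:
            pmat.setdefault(r.category_id, {})[q] = r.p
    df = pd.DataFrame(pmat).T.reindex(columns=cols)
    df = df.fillna(1.0)
    keep = (df < p_threshold).any(axis=1)
    df = df.loc[keep]
    if df.empty:
        raise ValueError("no category passes the retention filter")
    x = -np.log10(df.to_numpy(dtype=float))
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population SD (divide by n)
    flat = (sd[:, 0] == 0)
    if flat.any():
        logger.info("enrichment: %d zero-variance category rows set to z=0", flat.sum())
    z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=df.index, columns=cols)

    row_link = average(pdist(z, metric="euclidean")) if len(zdf) > 1 else None
    col_link = average(pdist(z.T, metric="euclidean")) if len(cols) > 1 else None
    row_order = list(zdf.index[leaves_list(row_link)]) if row_link is not None else list(zdf.index)
    col_order = [cols[i] for i in leaves_list(col_link)] if col_link is not None else cols
    return zdf, row_order, col_order, row_link, col_link


def dendrogram_newick(linkage_matrix, labels) -> str:
    """Serialise a SciPy linkage as a newick string with merge heights."""
    tree = to_tree(linkage_matrix)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
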
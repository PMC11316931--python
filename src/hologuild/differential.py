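"""Two-group differential abundance testing per omics feature.

Each feature is compared between the efficient and inefficient groups with
the Wilcoxon rank-sum (Mann–Whitney U) test — exact enumeration when both
groups have ≤ 10 samples and the data are tie-free, tie-corrected normal
approximation otherwise — followed by Benjamini–Hochberg adjustment across
all features of the layer.  Significant features are then cut into fold
change quartiles Q1–Q4 (Q4 = largest), and cross-layer relationships are
screened by pairwise Spearman correlation of significant features.

Fold change is log2 of the ratio of group means with a pseudo-count of
half the smallest nonzero value of the layer, so all-zero groups remain
finite.  Direction ``up`` means higher in the efficient group.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable

logger = logging.getLogger("hologuild")

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when both groups ≤ 10 with no ties; otherwise tie-corrected
    normal approximation with continuity correction.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # constant feature: flagged by caller
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(x) <= 10 and len(y) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_bh(table: FeatureTable, alpha: float = 0.05,
                pseudocount: float | None = None) -> pd.DataFrame:
    """Per-feature rank-sum tests with BH adjustment.

    Returns a DataFrame indexed by feature_id with columns ``log2_fold_change``
    (efficient over inefficient), ``p``, ``p_adj``, ``direction``
    (up = higher in efficient), ``constant`` flag and an empty ``quartile``
    column filled by :func:`fold_change_quartiles`.
    """
    eff = table.samples_in("efficient")
    ineff = table.samples_in("inefficient")
    if len(eff) < 2 or len(ineff) < 2:
        raise ValueError("both groups need at least two samples")
    ab = table.abundance
    x = ab[eff].to_numpy(dtype=float)
    y = ab[ineff].to_numpy(dtype=float)

    if pseudocount is None:
        nz = ab.to_numpy()[ab.to_numpy() > 0]
        pseudocount = 0.5 * nz.min() if nz.size else 0.5

    mean_eff = x.mean(axis=1)
    mean_ineff = y.mean(axis=1)
    log2fc = np.log2((mean_eff + pseudocount) / (mean_ineff + pseudocount))

    pvals = np.empty(ab.shape[0])
    constant = np.zeros(ab.shape[0], dtype=bool)
    for i in range(ab.shape[0]):
        row = np.concatenate([x[i], y[i]])
        if np.all(row == row[0]):
            pvals[i] = 1.0
            constant[i] = True
        else:
            pvals[i] = _rank_sum_p(x[i], y[i])
    if constant.any():
        logger.info("differential: %d constant features flagged (p=1)", constant.sum())

    p_adj = bh_adjust(pvals)
    res = pd.DataFrame({
        "log2_fold_change": log2fc,
        "p": pvals,
        "p_adj": p_adj,
        "direction": np.where(log2fc >= 0, "up", "down"),
        "constant": constant,
        "quartile": pd.Series([pd.NA] * ab.shape[0], dtype="object"),
    }, index=ab.index)
    res.index.name = "feature_id"
    return res


def fold_change_quartiles(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label significant features with fold-change quartiles Q1–Q4.

    Significant features (p_adj < alpha) are ranked by log2 fold change and
    cut at the empirical 25/50/75 percentiles; Q4 holds the largest fold
    changes.  Ties at a cut point fall to the lower quartile.  With fewer
    than four significant features quartiling is skipped with a warning.
    """
    res = results.copy()
    sig = res.index[res["p_adj"] < alpha]
    if len(sig) < 4:
        warnings.warn(f"only {len(sig)} significant features; quartiling skipped")
        return res
    fc = res.loc[sig, "log2_fold_change"].to_numpy(dtype=float)
    cuts = np.percentile(fc, [25, 50, 75])
    labels = np.select(
        [fc <= cuts[0], fc <= cuts[1], fc <= cuts[2]],
        ["Q1", "Q2", "Q3"], default="Q4")
    if np.all(fc == fc[0]):
        warnings.warn("all significant fold changes equal; all assigned Q1")
    res.loc[sig, "quartile"] = labels
    return res


def spearman_matrix(resultsA: pd.DataFrame, resultsB: pd.DataFrame,
                    tableA: FeatureTable, tableB: FeatureTable,
                    alpha: float = 0.05):
    """Spearman rho and p for every pair of significant A- and B-features.

    Samples are matched by shared sample id; at least four shared samples
    are required.  Returns (rho DataFrame, p DataFrame) with A-features in
    rows and B-features in columns.
    """
    shared = [s for s in tableA.sample_ids if s in set(tableB.sample_ids)]
    if len(shared) < 4:
        raise ValueError("need at least four shared samples")
    sigA = resultsA.index[resultsA["p_adj"] < alpha]
    sigB = resultsB.index[resultsB["p_adj"] < alpha]
    a = tableA.abundance.loc[sigA, shared].to_numpy(dtype=float)
    b = tableB.abundance.loc[sigB, shared].to_numpy(dtype=float)
    rho = np.zeros((len(sigA), len(sigB)))
    pv = np.ones_like(rho)
    for i in range(len(sigA)):
        for j in range(len(sigB)):
            r, p = stats.spearmanr(a[i], b[j])
            rho[i, j] = r
            pv[i, j] = p
    return (pd.DataFrame(rho, index=sigA, columns=sigB),
            pd.DataFrame(pv, index=sigA, columns=sigB))


def write_differential(results: pd.DataFrame, path) -> None:
    out = results[["log2_fold_change", "p", "p_adj", "quartile", "direction"]].copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
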
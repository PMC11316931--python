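"""Variant QC and mixed-model association scans for omics features.

Each omics feature (taxon abundance, protein or metabolite level) is
treated as a quantitative trait under the animal model

    y = 1λ + a + g·x + e,      a ~ N(0, G σ²_a),  e ~ N(0, I σ²_e)

with λ the overall mean, ``a`` the random additive genetic effect with
genomic relationship matrix G, and ``g`` the fixed per-allele effect of
the tested variant (coded −1/0/1 for AA/AB/BB).  Variance components are
estimated once by REML on the null model and reused for every marker
(the P3D strategy), so the scan is a sequence of generalized
least-squares fits sharing one spectral decomposition of G.

QC removes variants by minor allele frequency, missingness, and the exact
conditional Hardy–Weinberg test; kinship is the VanRaden genomic
relationship G = W Wᵀ / Σ 2p(1−p) on column-centered codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .differential import bh_adjust

logger = logging.getLogger("hologuild")


class EmptyPanelError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Animals × variants allele-count matrix coded −1/0/1 (NaN = missing)."""

    genotypes: np.ndarray               # float (n_animals, n_variants)
    variants: pd.DataFrame              # id, chrom, pos, a1, a2, maf
    sample_ids: list[str]

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=float)
        ok = np.isnan(g) | np.isin(g, (-1.0, 0.0, 1.0))
        if not ok.all():
            raise ValueError("genotypes must be coded -1/0/1 or missing")
        self.genotypes = g
        if g.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("genotype shape mismatch")
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant ids")

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the B allele (code +1 = BB)."""
        return (np.nanmean(self.genotypes, axis=0) + 1.0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(self.genotypes[:, mask],
                              self.variants.loc[mask].reset_index(drop=True),
                              list(self.sample_ids))


# ---------------------------------------------------------------------------
# Text I/O: PLINK .ped/.map and minimal VCF
# ---------------------------------------------------------------------------

_CODE_TO_ALLELES = {-1.0: ("A", "A"), 0.0: ("A", "B"), 1.0: ("B", "B")}


def write_plink(g: GenotypeMatrix, prefix: str) -> None:
    """White-space-delimited .ped/.map with alleles A/B; missing = 0 0."""
    with open(f"{prefix}.map", "w") as fh:
        for _, v in g.variants.iterrows():
            fh.write(f"{v['chrom']} {v['id']} 0 {int(v['pos'])}\n")
    with open(f"{prefix}.ped", "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = ["FAM", str(sid), "0", "0", "0", "-9"]
            for code in g.genotypes[i]:
                a, b = ("0", "0") if np.isnan(code) else _CODE_TO_ALLELES[code]
                fields.extend([a, b])
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    variants = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None,
                           names=["chrom", "id", "cm", "pos"], dtype={"id": str})
    rows, sample_ids = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            fields = line.split()
            sample_ids.append(fields[1])
            alleles = fields[6:]
            codes = []
            for j in range(0, len(alleles), 2):
                pair = (alleles[j], alleles[j + 1])
                if "0" in pair:
                    codes.append(np.nan)
                else:
                    codes.append(float(pair.count("B") - 1))
            rows.append(codes)
    geno = np.array(rows, dtype=float)
    vdf = pd.DataFrame({"id": variants["id"], "chrom": variants["chrom"],
                        "pos": variants["pos"], "a1": "A", "a2": "B"})
    vdf["maf"] = np.minimum((np.nanmean(geno, axis=0) + 1) / 2,
                            1 - (np.nanmean(geno, axis=0) + 1) / 2)
    return GenotypeMatrix(geno, vdf, sample_ids)


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Minimal VCF v4.2, GT field only."""
    gt_map = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in g.sample_ids) + "\n")
        for j, (_, v) in enumerate(g.variants.iterrows()):
            gts = ["./." if np.isnan(c) else gt_map[c] for c in g.genotypes[:, j]]
            fh.write(f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{v.get('a1', 'A')}\t"
                     f"{v.get('a2', 'B')}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    sample_ids: list[str] = []
    rows, meta = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            f = line.split("\t")
            meta.append({"id": f[2], "chrom": f[0], "pos": int(f[1]),
                         "a1": f[3], "a2": f[4]})
            codes = []
            for cell in f[9:]:
                gt = cell.split(":")[0].replace("|", "/")
                if "." in gt:
                    codes.append(np.nan)
                else:
                    codes.append(float(sum(int(x) for x in gt.split("/")) - 1))
            rows.append(codes)
    geno = np.array(rows, dtype=float).T
    vdf = pd.DataFrame(meta)
    p = (np.nanmean(geno, axis=0) + 1) / 2
    vdf["maf"] = np.minimum(p, 1 - p)
    return GenotypeMatrix(geno, vdf, sample_ids)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Sums probabilities of heterozygote counts (conditional on allele
    counts) no more probable than the observed count.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # log-probability of n_het heterozygotes given rare-allele count
    def logp(het: int) -> float:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        return (lgamma(n + 1) - lgamma(het + 1) - lgamma(hom_r + 1) - lgamma(hom_c + 1)
                + het * log(2.0) - (lgamma(2 * n + 1) - lgamma(rare + 1)
                                    - lgamma(2 * n - rare + 1)))
    hets = range(rare % 2, rare + 1, 2)
    logs = {h: logp(h) for h in hets if (rare - h) // 2 + (n - h - (rare - h) // 2) >= 0
            and n - h - (rare - h) // 2 >= 0}
    lobs = logs[n_het]
    probs = {h: np.exp(lp) for h, lp in logs.items()}
    total = sum(probs.values())
    tail = sum(p for h, p in probs.items() if logs[h] <= lobs + 1e-12)
    return min(1.0, tail / total)


def qc_variants(g: GenotypeMatrix, maf_min: float = 0.05,
                missing_max: float = 0.1, hwe_alpha: float = 1e-6):
    """Filter variants by MAF, missingness and exact HWE; returns (panel, report)."""
    geno = g.genotypes
    miss = np.isnan(geno).mean(axis=0)
    maf = g.maf()
    hwe_p = np.ones(g.n_variants)
    for j in range(g.n_variants):
        col = geno[:, j]
        col = col[~np.isnan(col)]
        n_hom1 = int((col == -1).sum())
        n_het = int((col == 0).sum())
        n_hom2 = int((col == 1).sum())
        hwe_p[j] = hwe_exact_p(n_het, n_hom1, n_hom2)
    fail_maf = maf < maf_min
    fail_miss = miss > missing_max
    fail_hwe = hwe_p < hwe_alpha
    keep = ~(fail_maf | fail_miss | fail_hwe)
    report = {"n_input": int(g.n_variants), "n_kept": int(keep.sum()),
              "fail_maf": int(fail_maf.sum()), "fail_missing": int(fail_miss.sum()),
              "fail_hwe": int(fail_hwe.sum())}
    logger.info("gwas QC: %s", report)
    if not keep.any():
        raise EmptyPanelError("all variants removed by QC")
    out = g.subset_variants(keep)
    out.variants = out.variants.assign(maf=maf[keep])
    return out, report


# ---------------------------------------------------------------------------
# Kinship and REML
# ---------------------------------------------------------------------------

def _impute_center(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing genotypes per variant and center columns."""
    col_mean = np.nanmean(geno, axis=0)
    w = np.where(np.isnan(geno), col_mean[None, :], geno)
    return w - col_mean[None, :], (col_mean + 1.0) / 2.0


def kinship(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship G = W Wᵀ / Σ 2 p_k (1 − p_k)."""
    w, p = _impute_center(g.genotypes)
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0:
        raise ValueError("degenerate panel: all variants monomorphic")
    return (w @ w.T) / c


@dataclass
class MixedModelFit:
    sigma_a2: float
    sigma_e2: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    reml_loglik: float
    h2: float = field(init=False)
    lambda_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        tot = self.sigma_a2 + self.sigma_e2
        self.h2 = self.sigma_a2 / tot if tot > 0 else 0.0
        self.lambda_ratio = (self.sigma_e2 / self.sigma_a2
                             if self.sigma_a2 > 0 else float("inf"))


def _reml_neg_loglik(h2: float, lam: np.ndarray, y_rot: np.ndarray,
                     x_rot: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over the total variance.

    Model V = σ²_p (h² Λ + (1 − h²) I) in the eigenbasis of G.
    """
    n, p = x_rot.shape
    w = h2 * lam + (1.0 - h2)
    if np.any(w <= 0):
        return np.inf
    wi = 1.0 / w
    xtwx = (x_rot * wi[:, None]).T @ x_rot
    xtwy = (x_rot * wi[:, None]).T @ y_rot
    beta = np.linalg.solve(xtwx, xtwy)
    r = y_rot - x_rot @ beta
    rss = float(r @ (wi * r))
    sigma2 = rss / (n - p)
    _, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(w)) + logdet_xtwx
                 + (n - p) * (1.0 + np.log(2.0 * np.pi)))
    return -ll


def fit_null_reml(trait, kin_or_eig, covariates=None) -> MixedModelFit:
    """REML variance components for y = 1λ + a + e via spectral decomposition.

    ``kin_or_eig`` is either the kinship matrix or a precomputed
    ``(eigenvalues, eigenvectors)`` pair (useful when many traits share one
    G).  The REML criterion is optimized in one dimension over h².
    """
    y = np.asarray(trait, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite trait values")
    if isinstance(kin_or_eig, tuple):
        lam, u = kin_or_eig
    else:
        kin = np.asarray(kin_or_eig, dtype=float)
        if kin.shape[0] != len(y):
            raise ValueError("trait length does not match kinship")
        lam, u = np.linalg.eigh(kin)
    lam = np.clip(lam, 0.0, None)
    x = np.ones((len(y), 1))
    if covariates is not None:
        x = np.column_stack([x, np.asarray(covariates, dtype=float)])
    y_rot = u.T @ y
    x_rot = u.T @ x

    obj = lambda h2: _reml_neg_loglik(h2, lam, y_rot, x_rot)
    res = optimize.minimize_scalar(obj, bounds=(1e-6, 1 - 1e-6), method="bounded",
                                   options={"xatol": 1e-8})
    # guard against local optima of the one-dimensional criterion
    grid = np.linspace(0.01, 0.99, 21)
    best = min([(obj(h), h) for h in grid] + [(res.fun, res.x)])
    if best[1] != res.x:
        res = optimize.minimize_scalar(
            obj, bounds=(max(best[1] - 0.05, 1e-6), min(best[1] + 0.05, 1 - 1e-6)),
            method="bounded", options={"xatol": 1e-8})
    h2 = float(res.x)
    n, p = x_rot.shape
    w = h2 * lam + (1 - h2)
    wi = 1.0 / w
    xtwx = (x_rot * wi[:, None]).T @ x_rot
    beta = np.linalg.solve(xtwx, (x_rot * wi[:, None]).T @ y_rot)
    r = y_rot - x_rot @ beta
    sigma_p2 = float(r @ (wi * r)) / (n - p)
    return MixedModelFit(h2 * sigma_p2, (1 - h2) * sigma_p2, lam, u, -float(res.fun))


def marker_scan(trait, g: GenotypeMatrix, fit: MixedModelFit,
                covariates=None) -> pd.DataFrame:
    """Per-variant GLS scan with variance components fixed at the null fit.

    Every variant is tested as a fixed effect in the rotated model with
    per-observation variances σ²_a λ_i + σ²_e; Wald two-sided p-values are
    BH-adjusted across the scan.  Missing genotypes are mean-imputed
    (matching the kinship treatment).  Variants constant after imputation
    get p = 1 and are flagged.
    """
    y = np.asarray(trait, dtype=float)
    u, lam = fit.eigenvectors, fit.eigenvalues
    d = fit.sigma_a2 * lam + fit.sigma_e2
    wi = 1.0 / d
    w, _ = _impute_center(g.genotypes)   # centered, imputed codes
    x0 = np.ones((len(y), 1))
    if covariates is not None:
        x0 = np.column_stack([x0, np.asarray(covariates, dtype=float)])
    y_rot = u.T @ y
    x0_rot = u.T @ x0
    xv_rot = u.T @ w                     # (n, M)

    # project the tested variant against the null design under the GLS metric
    a00 = (x0_rot * wi[:, None]).T @ x0_rot        # (p, p)
    a0v = (x0_rot * wi[:, None]).T @ xv_rot        # (p, M)
    a0y = (x0_rot * wi[:, None]).T @ y_rot         # (p,)
    svv = np.einsum("im,i,im->m", xv_rot, wi, xv_rot)
    svy = xv_rot.T @ (wi * y_rot)
    a00_inv = np.linalg.inv(a00)
    # Schur complement: variance and estimate of the marker effect
    denom = svv - np.einsum("pm,pq,qm->m", a0v, a00_inv, a0v)
    numer = svy - a0v.T @ (a00_inv @ a0y)
    const = denom <= 1e-12 * max(1.0, float(svv.max() if svv.size else 1.0))
    if const.any():
        logger.info("gwas scan: %d constant variants flagged (p=1)", const.sum())
    safe = np.where(const, 1.0, denom)
    beta = np.where(const, 0.0, numer / safe)
    se = np.where(const, np.nan, np.sqrt(1.0 / safe))
    z = np.where(const, 0.0, beta / np.where(const, 1.0, se))
    p = np.where(const, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    out = g.variants.copy().reset_index(drop=True)
    out = out.rename(columns={"id": "variant_id", "a1": "other_allele", "a2": "effect_allele"})
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["p_adj"] = bh_adjust(p)
    out["maf"] = g.maf()
    out["n"] = g.n_animals
    out["constant"] = const
    return out


def write_summary(summary: pd.DataFrame, path) -> None:
    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "beta", "se", "p", "p_adj", "maf", "n"]
    summary[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"variant_id": str})
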
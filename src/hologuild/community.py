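"""Diversity, ordination and permutation statistics.

Shannon and Chao1 alpha diversity, Bray–Curtis dissimilarity, PCA scores,
PERMANOVA (pseudo-F, R², permutation p), PERMDISP (homogeneity of group
dispersions) and the log2(pseudo-F/q) effect size used to compare the
discriminatory power of functional groups across omics layers.

Conventions: Shannon uses the natural logarithm; Chao1 is the classic
estimator with the F2 = 0 bias-corrected fallback; PERMANOVA permutes
whole-sample labels freely and includes the observed statistic in the
permutation p so p ≥ 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


class DegenerateInputError(ValueError):
    pass


class InvalidDesignError(ValueError):
    pass


def shannon(counts) -> float:
    """Shannon diversity H = −Σ p_i ln p_i over positive proportions."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or not (c > 0).any():
        raise DegenerateInputError("all-zero abundance vector")
    if (c < 0).any():
        raise ValueError("negative abundances")
    p = c[c > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1²/(2 F2), or S_obs + F1(F1−1)/2 when F2 = 0.

    F1 and F2 are the numbers of singletons and doubletons, so counts must
    be integers.
    """
    c = np.asarray(counts, dtype=float)
    if not np.allclose(c, np.round(c)):
        raise ValueError("chao1 requires integer counts")
    c = np.round(c).astype(int)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def bray_curtis(matrix) -> pd.DataFrame:
    """Bray–Curtis dissimilarity between sample rows.

    d(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i).  Bounded in [0, 1], symmetric,
    zero diagonal; not a metric (triangle inequality may fail).
    """
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        ids = list(range(x.shape[0]))
    if (x < 0).any():
        raise ValueError("negative abundances")
    row_sums = x.sum(axis=1)
    if np.any(row_sums == 0):
        # any pair involving an all-zero sample is 0/0
        raise DegenerateInputError("all-zero sample row; Bray-Curtis undefined")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=ids, columns=ids)


def pca_scores(matrix, n_components: int | None = None):
    """PCA on column-centered data via SVD.

    Returns (scores DataFrame, explained-variance fractions).  Fractions
    are non-increasing and sum to ≤ 1.
    """
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        ids = list(range(x.shape[0]))
    if x.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else var
    if n_components is not None:
        scores = scores[:, :n_components]
        frac = frac[:n_components]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=ids, columns=cols), frac


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_perm: float
    n_permutations: int
    q: float | None = None           # BH-adjusted p, filled across layers
    effect_size_log2: float | None = None

    def with_q(self, q: float) -> "PermanovaResult":
        self.q = q
        self.effect_size_log2 = effect_size_log2Fq(
            self.pseudo_F, q, q_floor=1.0 / (self.n_permutations + 1))
        return self


def _as_square(dist) -> tuple[np.ndarray, list]:
    if isinstance(dist, pd.DataFrame):
        return dist.to_numpy(dtype=float), list(dist.index)
    d = np.asarray(dist, dtype=float)
    return d, list(range(d.shape[0]))


def _group_codes(groups, ids) -> np.ndarray:
    if isinstance(groups, pd.Series):
        g = groups.reindex(ids).to_numpy()
    else:
        g = np.asarray(groups)
    codes, _ = pd.factorize(g)
    return codes


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, n_groups: int):
    """(pseudo-F, R²) for one label matrix of shape (P, N)."""
    n = d2.shape[0]
    ss_t = d2.sum() / (2.0 * n)
    ss_w = np.zeros(labels.shape[0])
    for g in range(n_groups):
        z = (labels == g).astype(float)
        within = np.einsum("pi,ij,pj->p", z, d2, z) / 2.0
        ss_w += within / z.sum(axis=1)
    ss_a = ss_t - ss_w
    df_a = n_groups - 1
    df_w = n - n_groups
    f = (ss_a / df_a) / (ss_w / df_w)
    r2 = ss_a / ss_t
    return f, r2


def permanova(dist, groups, n_perm: int = 999, seed=None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Sums of squares are decomposed from squared distances
    (SS_T = Σ_{i<j} d²_ij / N; within-group analogue per group);
    pseudo-F = (SS_A/(a−1)) / (SS_W/(N−a)); the permutation p counts label
    permutations with F ≥ F_obs, including the observed one, so
    p ∈ [1/(n_perm+1), 1].
    """
    d, ids = _as_square(dist)
    codes = _group_codes(groups, ids)
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise InvalidDesignError("need at least two group levels")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise InvalidDesignError("each group needs at least two members")
    d2 = d**2
    f_obs, r2_obs = _permanova_stats(d2, codes[None, :], n_groups)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    if n_perm > 0:
        f_perm, _ = _permanova_stats(d2, perms, n_groups)
        exceed = int(np.sum(f_perm >= f_obs[0]))
    else:
        exceed = 0
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(float(f_obs[0]), float(r2_obs[0]), float(p), n_perm)


def _pcoa_coords(d: np.ndarray) -> np.ndarray:
    """Principal-coordinate embedding; axes with negative eigenvalues dropped."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh((b + b.T) / 2)
    keep = w > 1e-10 * max(1.0, w.max())
    return v[:, keep] * np.sqrt(w[keep])


def permdisp(dist, groups, n_perm: int = 999, seed=None) -> tuple[float, float]:
    """PERMDISP: permutation test for homogeneity of group dispersions.

    Samples are embedded by principal coordinates (negative-eigenvalue axes
    dropped), each sample's Euclidean distance to its own group centroid is
    computed, and a one-way F on those distances is tested by permuting
    group labels.
    """
    d, ids = _as_square(dist)
    codes = _group_codes(groups, ids)
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise InvalidDesignError("need at least two group levels")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise InvalidDesignError("each group needs at least two members")
    coords = _pcoa_coords(d)
    z = np.empty(len(codes))
    for g in range(n_groups):
        members = codes == g
        centroid = coords[members].mean(axis=0)
        z[members] = np.linalg.norm(coords[members] - centroid, axis=1)

    def anova_f(labels: np.ndarray) -> np.ndarray:
        grand = z.mean()
        ss_b = np.zeros(labels.shape[0])
        ss_w = np.zeros(labels.shape[0])
        for g in range(n_groups):
            mask = labels == g
            ng = mask.sum(axis=1)
            means = (z[None, :] * mask).sum(axis=1) / ng
            ss_b += ng * (means - grand) ** 2
            ss_w += ((z[None, :] - means[:, None]) ** 2 * mask).sum(axis=1)
        n = len(z)
        num = ss_b / (n_groups - 1)
        den = ss_w / (n - n_groups)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
        return f

    f_obs = float(anova_f(codes[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    f_perm = anova_f(perms) if n_perm > 0 else np.array([])
    p = (1 + int(np.sum(f_perm >= f_obs))) / (1 + n_perm)
    return f_obs, float(p)


def effect_size_log2Fq(pseudo_F: float, q: float, q_floor: float | None = None) -> float:
    """log2(pseudo-F / q) effect size.

    ``q`` is the BH-adjusted permutation p (adjusted across the omics
    layers being compared); it is floored at 1/(n_perm+1) before division
    so the statistic stays finite.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    if q > 1:
        raise ValueError("q must be at most 1")
    if pseudo_F <= 0:
        raise ValueError("pseudo-F must be positive")
    if q_floor is not None:
        q = max(q, q_floor)
    return float(np.log2(pseudo_F / q))


def export_distance_matrix(dist: pd.DataFrame, path) -> None:
    dist.to_csv(path, sep="\t", float_format="%.10g")
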
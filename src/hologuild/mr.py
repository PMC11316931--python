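"""Two-sample Mendelian randomization: instruments, harmonization, estimators.

Genetic variants strongly associated with the exposure (a microbial taxon
abundance) serve as instrumental variables; their effects on exposure
(β_x, from one cohort's GWAS) and outcome (β_y, from another) combine into
a causal estimate through five estimators:

* IVW — inverse-variance-weighted meta-analysis of per-variant Wald
  ratios β_y/β_x, equivalently weighted regression through the origin;
  fixed-effect SE with multiplicative random-effect inflation when the
  Cochran Q exceeds its degrees of freedom.
* MR-Egger — weighted regression with a free intercept; the intercept
  estimates average directional pleiotropy and the slope is the
  bias-adjusted causal effect.
* Weighted median — consistent when up to half the weight comes from
  invalid instruments.
* Simple / weighted mode — kernel-density mode of the Wald ratios
  (largest cluster of agreeing instruments).

Bootstrap standard errors for the median/mode estimators use parametric
resampling of the summary statistics under a recorded seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("hologuild")

PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class HarmonizedInstruments:
    """Per-variant exposure/outcome effects aligned to the same allele."""

    data: pd.DataFrame  # variant_id, beta_exposure, se_exposure, beta_outcome, se_outcome

    def __post_init__(self) -> None:
        need = {"variant_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"harmonized table needs columns {sorted(need)}")
        if (self.data["beta_exposure"] == 0).any():
            zero = self.data.loc[self.data["beta_exposure"] == 0, "variant_id"].tolist()
            logger.warning("mr: dropping %d instruments with zero exposure beta", len(zero))
            self.data = self.data[self.data["beta_exposure"] != 0].reset_index(drop=True)

    @property
    def k(self) -> int:
        return len(self.data)

    @property
    def wald_ratios(self) -> np.ndarray:
        return (self.data["beta_outcome"] / self.data["beta_exposure"]).to_numpy()

    def arrays(self):
        d = self.data
        return (d["beta_exposure"].to_numpy(dtype=float),
                d["se_exposure"].to_numpy(dtype=float),
                d["beta_outcome"].to_numpy(dtype=float),
                d["se_outcome"].to_numpy(dtype=float))


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    ci95: tuple = field(init=False)
    egger_intercept: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        self.ci95 = (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


# ---------------------------------------------------------------------------
# Instrument selection and harmonization
# ---------------------------------------------------------------------------

def select_instruments(summary: pd.DataFrame, genos, p_adj_max: float = 0.001,
                       ld_r2_max: float = 0.1, use_adjusted: bool = True) -> list[str]:
    """Significant, LD-independent instruments.

    Variants below ``p_adj_max`` (on BH-adjusted p by default, raw p for
    the unadjusted-threshold convention used for metabolite exposures) are
    greedily pruned by ascending p so that no retained pair has genotype
    correlation² above ``ld_r2_max``.
    """
    col = "p_adj" if use_adjusted else "p"
    sig = summary[summary[col] < p_adj_max].sort_values([col, "p", "variant_id"])
    if sig.empty:
        raise InsufficientInstrumentsError("no variant passes the significance threshold")
    id_to_col = {vid: j for j, vid in enumerate(genos.variants["id"])}
    geno = genos.genotypes
    kept: list[str] = []
    kept_cols: list[np.ndarray] = []
    for vid in sig["variant_id"]:
        j = id_to_col.get(vid)
        if j is None:
            continue
        x = geno[:, j]
        x = np.where(np.isnan(x), np.nanmean(x), x)
        ok = True
        for other in kept_cols:
            if np.std(x) == 0 or np.std(other) == 0:
                continue
            r = np.corrcoef(x, other)[0, 1]
            if r * r > ld_r2_max:
                ok = False
                break
        if ok:
            kept.append(vid)
            kept_cols.append(x)
    if not kept:
        raise InsufficientInstrumentsError("LD pruning removed every instrument")
    return kept


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              exposure_freq: dict | None = None,
              outcome_freq: dict | None = None,
              freq_tol: float = 0.08) -> HarmonizedInstruments:
    """Align outcome effects to the exposure effect allele.

    Outcome betas are sign-flipped where the effect/other alleles are
    swapped relative to the exposure.  Strand-ambiguous (A/T, C/G)
    variants are dropped unless allele frequencies on both sides clearly
    agree (both away from 0.5 and on the same side).
    """
    exp = exposure.set_index("variant_id")
    out = outcome.set_index("variant_id")
    shared = exp.index.intersection(out.index)
    dropped = len(exp.index.union(out.index)) - len(shared)
    if dropped:
        logger.info("harmonize: %d variants absent from one side dropped", dropped)
    if len(shared) == 0:
        raise ValueError("no overlapping variants between exposure and outcome")
    rows = []
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        ea_e, oa_e = str(e["effect_allele"]), str(e["other_allele"])
        ea_o, oa_o = str(o["effect_allele"]), str(o["other_allele"])
        if frozenset((ea_e, oa_e)) in PALINDROMIC:
            fe = (exposure_freq or {}).get(vid)
            fo = (outcome_freq or {}).get(vid)
            ambiguous = True
            if fe is not None and fo is not None:
                if abs(fe - 0.5) > freq_tol and abs(fo - 0.5) > freq_tol \
                        and (fe - 0.5) * (fo - 0.5) > 0:
                    ambiguous = False
            if ambiguous:
                logger.info("harmonize: palindromic variant %s dropped", vid)
                continue
        if (ea_o, oa_o) == (ea_e, oa_e):
            flip = 1.0
        elif (ea_o, oa_o) == (oa_e, ea_e):
            flip = -1.0
        else:
            logger.info("harmonize: allele mismatch for %s, dropped", vid)
            continue
        rows.append({"variant_id": vid,
                     "beta_exposure": float(e["beta"]), "se_exposure": float(e["se"]),
                     "beta_outcome": flip * float(o["beta"]),
                     "se_outcome": float(o["se"]),
                     "effect_allele": ea_e, "other_allele": oa_e})
    if not rows:
        raise ValueError("no harmonizable variants")
    return HarmonizedInstruments(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def cochran_q(h: HarmonizedInstruments) -> tuple[float, int]:
    bx, _, by, sy = h.arrays()
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    q = float(np.sum(w * (by / bx - beta) ** 2))
    return q, h.k - 1


def ivw(h: HarmonizedInstruments) -> MREstimate:
    """Inverse-variance-weighted estimate (weighted regression through origin)."""
    if h.k < 1:
        raise InsufficientInstrumentsError("IVW needs at least one instrument")
    bx, _, by, sy = h.arrays()
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if h.k > 1:
        q, df = cochran_q(h)
        if q / df > 1.0:   # multiplicative random-effect inflation
            se *= float(np.sqrt(q / df))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MREstimate("IVW", beta, se, p, h.k)


def mr_egger(h: HarmonizedInstruments) -> MREstimate:
    """Egger regression: weighted fit of β_y on β_x with free intercept.

    Instruments are oriented so that β_x ≥ 0 (the estimate is invariant to
    allele orientation only after this convention).  The intercept tests
    average directional pleiotropy.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least three instruments")
    bx, _, by, sy = h.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = (x * w[:, None]).T @ x
    coef = np.linalg.solve(xtwx, (x * w[:, None]).T @ by)
    resid = by - x @ coef
    dof = h.k - 2
    scale = float(resid @ (w * resid)) / dof if dof > 0 else 0.0
    cov = np.linalg.inv(xtwx) * scale
    se_int, se_slope = np.sqrt(np.diag(cov))
    t_slope = coef[1] / se_slope if se_slope > 0 else np.inf
    t_int = coef[0] / se_int if se_int > 0 else np.inf
    p_slope = float(2.0 * stats.t.sf(abs(t_slope), dof))
    p_int = float(2.0 * stats.t.sf(abs(t_int), dof))
    est = MREstimate("Egger", float(coef[1]), float(se_slope), p_slope, h.k)
    est.egger_intercept = float(coef[0])
    est.intercept_p = p_int
    return est


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _parametric_boot_se(h: HarmonizedInstruments, point_fn, n_boot: int, seed):
    if n_boot <= 0:
        return float("nan")
    bx, sx, by, sy = h.arrays()
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb = np.where(bxb == 0, 1e-12, bxb)
        boots[b] = point_fn(byb / bxb, bxb, byb)
    return float(np.std(boots, ddof=1))


def weighted_median(h: HarmonizedInstruments, n_boot: int = 1000, seed=None) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Wald ratios are ordered and the 50% crossing of cumulative
    standardized inverse-variance weights is linearly interpolated; the
    estimate is consistent when invalid instruments carry < 50% of weight.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError("weighted median needs at least three instruments")
    bx, _, by, sy = h.arrays()
    weights = bx**2 / sy**2
    beta = _weighted_median_point(by / bx, weights)
    se = _parametric_boot_se(
        h, lambda r, bxb, byb: _weighted_median_point(r, bxb**2 / sy**2), n_boot, seed)
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return MREstimate("weighted_median", beta, se, p, h.k)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    sd = np.std(ratios, ddof=1) if len(ratios) > 1 else 0.0
    mad = stats.median_abs_deviation(ratios, scale="normal")
    scale_est = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    if scale_est == 0:
        return float(np.median(ratios))
    h_bw = bandwidth_factor * 0.9 * scale_est * len(ratios) ** (-1 / 5)
    grid = np.linspace(ratios.min() - 3 * h_bw, ratios.max() + 3 * h_bw, 1024)
    dens = (weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h_bw) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_based(h: HarmonizedInstruments, weighted: bool = True,
               bandwidth_factor: float = 1.0, n_boot: int = 1000, seed=None) -> MREstimate:
    """Mode-based estimate: normal-kernel density argmax over Wald ratios.

    Bandwidth follows the modified Silverman rule
    0.9 · min(SD, MAD) · k^(−1/5) scaled by ``bandwidth_factor``; the
    weighted variant uses inverse-variance weights in the kernel sum.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError("mode-based estimate needs at least three instruments")
    bx, _, by, sy = h.arrays()
    weights = bx**2 / sy**2 if weighted else np.ones(h.k)
    beta = _mode_point(by / bx, weights, bandwidth_factor)

    def point(r, bxb, byb):
        w = bxb**2 / sy**2 if weighted else np.ones(len(r))
        return _mode_point(r, w, bandwidth_factor)

    se = _parametric_boot_se(h, point, n_boot, seed)
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return MREstimate("weighted_mode" if weighted else "simple_mode", beta, se, p, h.k)


def mr_report(h: HarmonizedInstruments, n_boot: int = 1000, seed=None):
    """All five estimators plus Cochran heterogeneity Q.

    With a single instrument only the IVW/Wald ratio is computable; the
    other methods are reported as None.
    """
    rng = np.random.default_rng(seed)
    estimates: dict[str, MREstimate | None] = {}
    estimates["IVW"] = ivw(h)
    for name, fn in (
        ("Egger", lambda: mr_egger(h)),
        ("weighted_median", lambda: weighted_median(h, n_boot, rng.integers(2**31 - 1))),
        ("simple_mode", lambda: mode_based(h, False, 1.0, n_boot, rng.integers(2**31 - 1))),
        ("weighted_mode", lambda: mode_based(h, True, 1.0, n_boot, rng.integers(2**31 - 1))),
    ):
        try:
            estimates[name] = fn()
        except InsufficientInstrumentsError as err:
            logger.info("mr: %s unavailable (%s)", name, err)
            estimates[name] = None
    q, df = cochran_q(h) if h.k > 1 else (0.0, 0)
    return estimates, q, df


def report_frame(estimates: dict, q: float, q_df: int,
                 exposure: str = "", outcome: str = "") -> pd.DataFrame:
    rows = []
    for name, est in estimates.items():
        if est is None:
            continue
        rows.append({
            "exposure": exposure, "outcome": outcome, "method": name,
            "n_snps": est.n_snps, "beta": est.beta, "se": est.se,
            "ci_low": est.ci95[0], "ci_high": est.ci95[1], "p": est.p,
            "egger_intercept": est.egger_intercept, "intercept_p": est.intercept_p,
            "Q": q, "Q_df": q_df})
    return pd.DataFrame(rows)
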
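"""Linear mediation decomposition with case-resampling bootstrap inference.

For the chain exposure (taxon) → mediator (protein/metabolite) → outcome
(feed-efficiency phenotype), two OLS fits

    m = α₀ + a·x (+ covariates)
    y = β₀ + c′·x + b·m (+ covariates)

give the average causal mediation effect ACME = a·b, the average direct
effect ADE = c′, and the total effect from y ~ x.  In the linear
no-interaction case the decomposition total = ACME + ADE holds exactly on
the point estimates.  Inference is by nonparametric bootstrap: rows are
resampled with replacement, both models refit, and two-sided percentile
p-values computed; under a fixed seed results are reproducible and
p ≥ 2/(n_boot + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateExposureError(ValueError):
    pass


@dataclass
class MediationEstimate:
    acme: float
    ade: float
    total: float
    prop_mediated: float | None
    p_acme: float
    p_ade: float
    p_total: float
    n_boot: int
    seed: object = None


def _batched_ols_coefs(x_design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients for a batch of designs (B, n, p) against (B, n)."""
    xtx = np.einsum("bnp,bnq->bpq", x_design, x_design)
    xty = np.einsum("bnp,bn->bp", x_design, y)
    return np.linalg.solve(xtx, xty[..., None])[..., 0]


def _percentile_p(boots: np.ndarray) -> float:
    """Two-sided bootstrap percentile p with the +1 convention (never 0)."""
    b = len(boots)
    n_le = int(np.sum(boots <= 0))
    n_ge = int(np.sum(boots >= 0))
    return float(min(1.0, 2.0 * (1 + min(n_le, n_ge)) / (b + 1)))


def fit_mediation(exposure, mediator, outcome, covariates=None,
                  n_boot: int = 1000, seed=None) -> MediationEstimate:
    """Estimate ACME, ADE, total effect, and bootstrap p-values.

    ``covariates`` (optional, n × q) enter both models.  ``n_boot = 0``
    skips the bootstrap and returns point estimates with p = NaN.
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(x)
    if not (len(m) == n and len(y) == n):
        raise ValueError("exposure, mediator, outcome must have equal length")
    if n < 10:
        raise ValueError("mediation requires at least 10 observations")
    if not (np.isfinite(x).all() and np.isfinite(m).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0:
        raise DegenerateExposureError("constant exposure")
    if n_boot and n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap p-values")

    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]

    def decompose(xs, ms, ys, cs):
        ones = np.ones_like(xs)
        dm = np.column_stack([ones, xs] + ([cs] if cs is not None else []))
        dy = np.column_stack([ones, xs, ms] + ([cs] if cs is not None else []))
        dt = np.column_stack([ones, xs] + ([cs] if cs is not None else []))
        a = np.linalg.lstsq(dm, ms, rcond=None)[0][1]
        coef_y = np.linalg.lstsq(dy, ys, rcond=None)[0]
        c_prime, b = coef_y[1], coef_y[2]
        total = np.linalg.lstsq(dt, ys, rcond=None)[0][1]
        return a * b, c_prime, total

    acme, ade, total = decompose(x, m, y, cov)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        xb, mb, yb = x[idx], m[idx], y[idx]
        ones = np.ones((n_boot, n, 1))
        cb = cov[idx] if cov is not None else None
        parts_m = [ones, xb[..., None]] + ([cb] if cb is not None else [])
        parts_y = [ones, xb[..., None], mb[..., None]] + ([cb] if cb is not None else [])
        dm = np.concatenate(parts_m, axis=2)
        dy = np.concatenate(parts_y, axis=2)
        a_b = _batched_ols_coefs(dm, mb)[:, 1]
        coef_y_b = _batched_ols_coefs(dy, yb)
        acme_b = a_b * coef_y_b[:, 2]
        ade_b = coef_y_b[:, 1]
        total_b = acme_b + ade_b  # exact OLS identity per resample
        p_acme = _percentile_p(acme_b)
        p_ade = _percentile_p(ade_b)
        p_total = _percentile_p(total_b)
    else:
        p_acme = p_ade = p_total = float("nan")

    prop = acme / total if abs(total) >= 1e-8 else None
    if prop is None:
        warnings.warn("total effect near zero; proportion mediated undefined")
    return MediationEstimate(float(acme), float(ade), float(total), prop,
                             p_acme, p_ade, p_total, n_boot, seed)


def mediation_frame(est: MediationEstimate, exposure="", mediator="", outcome="") -> pd.DataFrame:
    return pd.DataFrame([{
        "exposure": exposure, "mediator": mediator, "outcome": outcome,
        "acme": est.acme, "ade": est.ade, "total": est.total,
        "prop_mediated": est.prop_mediated, "p_acme": est.p_acme,
        "p_ade": est.p_ade, "p_total": est.p_total,
        "n_boot": est.n_boot, "seed": est.seed}])
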
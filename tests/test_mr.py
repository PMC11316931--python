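import numpy as np
import pandas as pd
import pytest

from hologuild.gwas import GenotypeMatrix
from hologuild.mr import (HarmonizedInstruments, InsufficientInstrumentsError,
                          cochran_q, harmonize, ivw, mode_based, mr_egger,
                          mr_report, select_instruments, weighted_median)


def _h(bx, by, sy, sx=None):
    bx = np.asarray(bx, dtype=float)
    k = len(bx)
    return HarmonizedInstruments(pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(k)],
        "beta_exposure": bx,
        "se_exposure": np.full(k, 0.01) if sx is None else np.asarray(sx, float),
        "beta_outcome": np.asarray(by, dtype=float),
        "se_outcome": np.asarray(sy, dtype=float),
    }))


def _summary(ids, betas, ps, alleles=None):
    k = len(ids)
    alleles = alleles or [("B", "A")] * k
    return pd.DataFrame({
        "variant_id": ids, "chrom": 1, "pos": np.arange(k),
        "effect_allele": [a[0] for a in alleles],
        "other_allele": [a[1] for a in alleles],
        "beta": betas, "se": 0.05, "p": ps, "p_adj": ps,
        "maf": 0.3, "n": 100})


class TestSelectInstruments:
    def _genos(self, geno):
        geno = np.asarray(geno, dtype=float)
        n, m = geno.shape
        variants = pd.DataFrame({"id": [f"v{i}" for i in range(m)], "chrom": 1,
                                 "pos": np.arange(m), "a1": "A", "a2": "B",
                                 "maf": 0.3})
        return GenotypeMatrix(geno, variants, [f"s{i}" for i in range(n)])

    def test_correlated_pair_pruned_to_best(self, rng):
        col = rng.integers(-1, 2, size=100).astype(float)
        g = self._genos(np.column_stack([col, col]))
        summary = _summary(["v0", "v1"], [0.5, 0.4], [1e-6, 1e-4])
        kept = select_instruments(summary, g, p_adj_max=0.001)
        assert kept == ["v0"]

    def test_independent_variants_all_kept(self, rng):
        m = 28
        geno = rng.integers(-1, 2, size=(500, m)).astype(float)
        g = self._genos(geno)
        summary = _summary([f"v{i}" for i in range(m)], [0.3] * m, [1e-5] * m)
        kept = select_instruments(summary, g, p_adj_max=0.001)
        assert len(kept) == 28

    def test_zero_threshold_rejected(self, rng):
        g = self._genos(rng.integers(-1, 2, size=(50, 3)).astype(float))
        summary = _summary(["v0", "v1", "v2"], [0.3] * 3, [1e-5] * 3)
        with pytest.raises(InsufficientInstrumentsError):
            select_instruments(summary, g, p_adj_max=0.0)


class TestHarmonize:
    def test_swapped_alleles_flip_beta(self):
        exp = _summary(["v0"], [0.5], [1e-5], alleles=[("G", "C")])
        # palindromic G/C would be dropped; use non-palindromic pair
        exp = _summary(["v0"], [0.5], [1e-5], alleles=[("G", "A")])
        out = _summary(["v0"], [0.3], [0.01], alleles=[("A", "G")])
        h = harmonize(exp, out)
        assert h.data["beta_outcome"].iloc[0] == pytest.approx(-0.3)

    def test_identical_coding_unchanged(self):
        exp = _summary(["v0"], [0.5], [1e-5], alleles=[("G", "A")])
        out = _summary(["v0"], [0.3], [0.01], alleles=[("G", "A")])
        h = harmonize(exp, out)
        assert h.data["beta_outcome"].iloc[0] == pytest.approx(0.3)

    def test_palindromic_dropped_without_freq(self):
        exp = _summary(["v0", "v1"], [0.5, 0.4], [1e-5, 1e-5],
                       alleles=[("A", "T"), ("G", "A")])
        out = _summary(["v0", "v1"], [0.3, 0.2], [0.01, 0.01],
                       alleles=[("A", "T"), ("G", "A")])
        h = harmonize(exp, out)
        assert list(h.data["variant_id"]) == ["v1"]

    def test_no_overlap_rejected(self):
        exp = _summary(["v0"], [0.5], [1e-5])
        out = _summary(["v9"], [0.3], [0.01])
        with pytest.raises(ValueError, match="overlap"):
            harmonize(exp, out)


class TestIVW:
    def test_single_instrument_wald_ratio(self):
        est = ivw(_h([0.5], [0.1], [0.05]))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_consensus_ratio(self):
        est = ivw(_h([0.2, 0.5, 0.9], [0.04, 0.10, 0.18], [0.05, 0.02, 0.07]))
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_matches_wls_through_origin(self):
        bx = np.array([0.4, 0.5, 0.3])
        by = np.array([0.12, 0.10, 0.03])
        sy = np.array([0.05, 0.04, 0.06])
        est = ivw(_h(bx, by, sy))
        w = 1.0 / sy**2
        ref = np.sum(w * bx * by) / np.sum(w * bx * bx)
        assert est.beta == pytest.approx(ref, abs=1e-10)

    def test_ci_follows_normal_convention(self):
        est = ivw(_h([0.5], [0.1], [0.05]))
        assert est.ci95[0] == pytest.approx(est.beta - 1.96 * est.se)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        by = 0.1 + 0.3 * bx
        est = mr_egger(_h(bx, by, [0.05] * 4))
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert est.se == pytest.approx(0.0, abs=1e-8)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(_h([0.5, 0.4], [0.1, 0.1], [0.05, 0.05]))


class TestWeightedMedian:
    def test_equal_weight_interpolation(self):
        est = weighted_median(_h([1.0, 1.0, 1.0], [0.1, 0.2, 0.9],
                                 [0.05, 0.05, 0.05]), n_boot=0)
        assert est.beta == pytest.approx(0.2)

    def test_consensus(self):
        est = weighted_median(_h([0.2, 0.5, 0.9],
                                 [0.2 * 0.3, 0.5 * 0.3, 0.9 * 0.3],
                                 [0.05, 0.02, 0.07]), n_boot=0)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    def test_within_ratio_range(self, rng):
        for _ in range(20):
            bx = rng.uniform(0.2, 0.8, size=7)
            by = rng.normal(0.3 * bx, 0.05)
            sy = rng.uniform(0.02, 0.08, size=7)
            est = weighted_median(_h(bx, by, sy), n_boot=0)
            ratios = by / bx
            assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12

    def test_bootstrap_reproducible(self):
        h = _h([0.3, 0.5, 0.7], [0.1, 0.14, 0.22], [0.04, 0.05, 0.06])
        e1 = weighted_median(h, n_boot=200, seed=42)
        e2 = weighted_median(h, n_boot=200, seed=42)
        assert e1.se == e2.se


class TestModeBased:
    def test_consensus(self):
        est = mode_based(_h([0.2, 0.5, 0.9], [0.2 * 0.4, 0.5 * 0.4, 0.9 * 0.4],
                            [0.05, 0.02, 0.07]), n_boot=0)
        assert est.beta == pytest.approx(0.4, abs=1e-6)

    def test_majority_cluster_wins(self, rng):
        ratios = np.r_[rng.normal(0.2, 0.01, 7), rng.normal(0.9, 0.01, 3)]
        bx = np.ones(10)
        est = mode_based(_h(bx, ratios, [0.05] * 10), weighted=False, n_boot=0)
        assert 0.17 <= est.beta <= 0.23

    def test_weighted_equals_simple_with_equal_weights(self):
        h = _h([0.5, 0.5, 0.5, 0.5], [0.1, 0.12, 0.15, 0.3], [0.05] * 4)
        simple = mode_based(h, weighted=False, n_boot=0)
        weighted = mode_based(h, weighted=True, n_boot=0)
        assert simple.beta == pytest.approx(weighted.beta, abs=1e-9)


class TestReportAndProperties:
    def test_consensus_all_methods_agree(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        h = _h(bx, 0.25 * bx, [0.04] * 5)
        estimates, q, q_df = mr_report(h, n_boot=100, seed=0)
        for est in estimates.values():
            assert est.beta == pytest.approx(0.25, abs=1e-4)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert q_df == 4

    def test_single_instrument_only_ivw(self):
        estimates, _, _ = mr_report(_h([0.5], [0.1], [0.05]), n_boot=0)
        assert estimates["IVW"] is not None
        assert estimates["Egger"] is None
        assert estimates["weighted_median"] is None

    def test_scale_equivariance(self):
        bx = np.array([0.3, 0.5, 0.7, 0.9])
        by = np.array([0.10, 0.14, 0.22, 0.25])
        sy = np.array([0.04, 0.05, 0.06, 0.05])
        c = 2.5
        for fn in (ivw,
                   mr_egger,
                   lambda h: weighted_median(h, n_boot=0),
                   lambda h: mode_based(h, n_boot=0)):
            e1 = fn(_h(bx, by, sy))
            e2 = fn(_h(c * bx, by, sy))
            assert e2.beta == pytest.approx(e1.beta / c, rel=1e-6)
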
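import numpy as np
import pandas as pd
import pytest

from hologuild.gwas import (EmptyPanelError, GenotypeMatrix, fit_null_reml,
                            hwe_exact_p, kinship, marker_scan, qc_variants,
                            read_plink, read_vcf, write_plink, write_vcf,
                            MixedModelFit, _reml_neg_loglik)
from hologuild.synthetic import CohortConfig, simulate_causal_chain, simulate_genotypes


def _matrix(geno, mafs=None):
    geno = np.asarray(geno, dtype=float)
    n, m = geno.shape
    variants = pd.DataFrame({"id": [f"v{j}" for j in range(m)], "chrom": 1,
                             "pos": np.arange(m) + 1, "a1": "A", "a2": "B",
                             "maf": mafs if mafs is not None else 0.5})
    return GenotypeMatrix(geno, variants, [f"s{i}" for i in range(n)])


class TestGenotypeIO:
    def test_plink_round_trip(self, tmp_path, small_config):
        g = simulate_genotypes(small_config)
        write_plink(g, str(tmp_path / "geno"))
        back = read_plink(str(tmp_path / "geno"))
        assert np.array_equal(back.genotypes, g.genotypes)
        assert list(back.variants["id"]) == list(g.variants["id"])
        assert back.sample_ids == g.sample_ids

    def test_vcf_round_trip(self, tmp_path):
        g = _matrix([[-1, 0, np.nan], [1, 0, -1]])
        write_vcf(g, str(tmp_path / "g.vcf"))
        back = read_vcf(str(tmp_path / "g.vcf"))
        assert np.array_equal(np.nan_to_num(back.genotypes, nan=9),
                              np.nan_to_num(g.genotypes, nan=9))

    def test_invalid_coding_rejected(self):
        with pytest.raises(ValueError, match="coded"):
            _matrix([[2.0, 0.0]])


class TestQC:
    def test_hwe_equilibrium_retained(self):
        # (AA, AB, BB) = (25, 50, 25): textbook equilibrium, p near 1
        assert hwe_exact_p(50, 25, 25) > 0.5
        geno = np.concatenate([[-1.0] * 25, [0.0] * 50, [1.0] * 25])
        g = _matrix(geno[:, None])
        kept, report = qc_variants(g, maf_min=0.01, hwe_alpha=1e-3)
        assert report["n_kept"] == 1

    def test_hwe_extreme_disequilibrium_removed(self):
        # all heterozygous: maximally far from equilibrium
        g = _matrix(np.concatenate([np.zeros(100), [-1.0] * 2, [1.0] * 2])[:, None])
        with pytest.raises(EmptyPanelError):
            qc_variants(g, maf_min=0.01, hwe_alpha=1e-3)

    def test_monomorphic_removed(self):
        g = _matrix(np.column_stack([np.full(50, -1.0),
                                     np.resize([-1.0, 0.0, 1.0, 0.0], 50)]))
        kept, report = qc_variants(g, maf_min=0.01, hwe_alpha=1e-12)
        assert report["fail_maf"] == 1 and report["n_kept"] == 1

    def test_high_missingness_removed(self):
        col = np.resize([-1.0, 0.0, 1.0, 0.0], 40)
        missing = col.copy()
        missing[:20] = np.nan
        g = _matrix(np.column_stack([col, missing]))
        kept, report = qc_variants(g, maf_min=0.01, missing_max=0.1, hwe_alpha=1e-12)
        assert report["fail_missing"] == 1 and kept.n_variants == 1


class TestKinship:
    def test_identical_animals_maximal_relationship(self, rng):
        row = rng.integers(-1, 2, size=200).astype(float)
        others = rng.integers(-1, 2, size=(4, 200)).astype(float)
        g = _matrix(np.vstack([row, row, others]))
        k = kinship(g)
        # duplicated animals: off-diagonal entry equals both diagonals
        assert k[0, 1] == pytest.approx(k[0, 0])
        assert k[0, 1] == pytest.approx(k[1, 1])
        assert k[0, 1] > k[:2, 2:].max()  # exceeds every unrelated pairing

    def test_unrelated_animals_near_zero(self):
        # column centering forces E[off-diagonal] toward -1/(n-1), so the
        # mean shrinks to 0 only with enough animals as well as variants
        cfg = CohortConfig(n_animals=200, n_variants=5000, n_causal_variants=5,
                           seed=4)
        k = kinship(simulate_genotypes(cfg))
        off = k[np.triu_indices(200, 1)]
        assert abs(off.mean()) < 0.02

    def test_symmetric_psd(self, small_config):
        k = kinship(simulate_genotypes(small_config))
        assert np.allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() >= -1e-8


class TestREML:
    def test_null_trait_gives_tiny_genetic_variance(self, small_config, rng):
        k = kinship(simulate_genotypes(small_config))
        h2s = []
        for _ in range(5):
            fit = fit_null_reml(rng.normal(size=small_config.n_animals), k)
            h2s.append(fit.h2)
        assert np.median(h2s) < 0.25

    def test_optimum_beats_grid(self, small_config, rng):
        k = kinship(simulate_genotypes(small_config))
        lam, u = np.linalg.eigh(k)
        y = rng.normal(size=small_config.n_animals)
        fit = fit_null_reml(y, k)
        y_rot = fit.eigenvectors.T @ y
        x_rot = fit.eigenvectors.T @ np.ones((len(y), 1))
        best = _reml_neg_loglik(fit.h2, np.clip(fit.eigenvalues, 0, None),
                                y_rot, x_rot)
        for h2 in np.linspace(0.02, 0.98, 21):
            assert best <= _reml_neg_loglik(h2, np.clip(fit.eigenvalues, 0, None),
                                            y_rot, x_rot) + 1e-6

    def test_non_finite_trait_rejected(self, small_config):
        k = kinship(simulate_genotypes(small_config))
        y = np.zeros(small_config.n_animals)
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_null_reml(y, k)


class TestMarkerScan:
    def _ols_oracle(self, y, x, sigma2):
        """Per-marker OLS with the residual variance fixed at sigma2."""
        d = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(d, y, rcond=None)[0]
        cov = sigma2 * np.linalg.inv(d.T @ d)
        return beta[1], np.sqrt(cov[1, 1])

    def test_identity_kinship_reduces_to_ols(self, rng):
        n, m = 120, 30
        geno = rng.integers(-1, 2, size=(n, m)).astype(float)
        g = _matrix(geno)
        y = rng.normal(size=n)
        sigma2 = 1.3
        fit = MixedModelFit(0.0, sigma2, np.ones(n), np.eye(n), 0.0)
        out = marker_scan(y, g, fit)
        for j in range(m):
            x = geno[:, j]
            if np.all(x == x[0]):
                continue
            b_ref, se_ref = self._ols_oracle(y, x, sigma2)
            assert out["beta"].iloc[j] == pytest.approx(b_ref, rel=1e-8)
            assert out["se"].iloc[j] == pytest.approx(se_ref, rel=1e-8)

    def test_affine_trait_rescaling_preserves_p(self, small_config):
        g = simulate_genotypes(small_config)
        rng = np.random.default_rng(2)
        y = rng.normal(size=small_config.n_animals)
        k = kinship(g)
        fit1 = fit_null_reml(y, k)
        fit2 = fit_null_reml(3.0 * y + 7.0, k)
        p1 = marker_scan(y, g, fit1)["p"]
        p2 = marker_scan(3.0 * y + 7.0, g, fit2)["p"]
        assert np.allclose(p1, p2, atol=1e-6)

    def test_constant_variant_flagged(self, rng):
        n = 60
        geno = np.column_stack([np.full(n, 1.0),
                                rng.integers(-1, 2, size=n).astype(float)])
        g = _matrix(geno)
        fit = MixedModelFit(0.0, 1.0, np.ones(n), np.eye(n), 0.0)
        out = marker_scan(rng.normal(size=n), g, fit)
        assert bool(out["constant"].iloc[0])
        assert out["p"].iloc[0] == 1.0

    def test_bh_never_reorders_p(self, small_config, rng):
        g = simulate_genotypes(small_config)
        y = rng.normal(size=small_config.n_animals)
        fit = fit_null_reml(y, kinship(g))
        out = marker_scan(y, g, fit).sort_values("p")
        assert (np.diff(out["p_adj"]) >= -1e-12).all()


class TestCausalChainSimulation:
    def test_null_chain_uncorrelated(self):
        cfg = CohortConfig(n_animals=2000, n_variants=50, n_causal_variants=5,
                           theta_taxon_to_mediator=0.0,
                           delta_mediator_to_phenotype=0.0, gamma_direct=0.0,
                           seed=8)
        g = simulate_genotypes(cfg)
        taxon, _, phen, _ = simulate_causal_chain(g, cfg)
        r = np.corrcoef(taxon, phen)[0, 1]
        assert abs(r) < 3 / np.sqrt(cfg.n_animals)

    def test_noise_free_mediator_is_scaled_taxon(self):
        cfg = CohortConfig(n_animals=200, n_variants=50, n_causal_variants=5,
                           theta_taxon_to_mediator=0.5, noise_sd=0.0,
                           pleiotropy_frac=0.0, seed=9)
        g = simulate_genotypes(cfg)
        taxon, mediator, _, _ = simulate_causal_chain(g, cfg)
        assert np.allclose(mediator, 0.5 * taxon)

    def test_variance_partition_matches_h2(self):
        cfg = CohortConfig(n_animals=5000, n_variants=300, n_causal_variants=30,
                           taxon_h2=0.3, seed=10)
        g = simulate_genotypes(cfg)
        taxon, _, _, truth = simulate_causal_chain(g, cfg)
        score = sum(truth.variant_effects[v]
                    * g.genotypes[:, list(g.variants["id"]).index(v)]
                    for v in truth.causal_variant_ids)
        r2 = np.corrcoef(score, taxon)[0, 1] ** 2
        assert r2 == pytest.approx(0.30, abs=0.02)
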
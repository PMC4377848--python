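import numpy as np
import pandas as pd
import pytest

from fagwas.association import (_reml_neg2, build_design, compute_qvalues,
                                estimate_pi0, fit_null_model, scan_snps,
                                significance_threshold_neglogp,
                                variance_explained)
from fagwas.core_io import PhenotypeTable
from fagwas.grm import GRMatrix, compute_grm
from fagwas.simulate import (SimulationConfig, TraitSpec, simulate_genotypes,
                             simulate_phenotypes)
from conftest import make_genos, make_pheno


def identity_grm(samples):
    """GRM of unrelated animals: the mixed model collapses to OLS when
    sigma_a^2 is 0 or G = I."""
    n = len(samples)
    return GRMatrix(list(samples), np.eye(n), 1.0, ["1"])


class TestNullModel:
    def test_ols_limit_on_hand_checkable_table(self):
        # 12 animals, G = I: REML residual variance equals the OLS MSE
        rng = np.random.default_rng(21)
        ph = make_pheno(12, {"y": rng.normal(size=12)}, seed=21)
        fit = fit_null_model(ph, identity_grm([f"s{i}" for i in range(12)]), "y")
        X, _ = build_design(ph)
        y = ph.trait("y")
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        mse = resid @ resid / (12 - X.shape[1])
        # with G = I only the total sigma_a + sigma_e is identified
        assert fit.total_var == pytest.approx(mse, rel=1e-4)

    def test_optimum_beats_fine_grid(self, sim_cohort):
        _, genos, pheno = sim_cohort
        grm = compute_grm(genos)
        fit = fit_null_model(pheno, grm, "y")
        S, U = fit.eigvals, fit.eigvecs
        Xr, yr = U.T @ fit.X, U.T @ fit.y
        at_opt = _reml_neg2(fit.h2, S, Xr, yr)
        grid = np.linspace(0.0, 0.98, 50)
        assert at_opt <= min(_reml_neg2(h, S, Xr, yr) for h in grid) + 1e-6

    def test_h2_recovery(self):
        h2s = []
        for s in range(10):
            cfg = SimulationConfig(
                n_animals=400, n_snps=2000,
                traits=[TraitSpec("y", qtl=[], h2=0.5)], seed=600 + s)
            g = simulate_genotypes(cfg)
            ph = simulate_phenotypes(g, cfg)
            fit = fit_null_model(ph, compute_grm(g), "y")
            # per-replicate REML noise is large for near-unrelated samples
            # (sampling sd ~ 0.16 at this design); the estimator is unbiased
            assert abs(fit.h2 - 0.5) < 0.45
            h2s.append(fit.h2)
        assert abs(np.mean(h2s) - 0.5) < 0.10

    def test_zero_variance_component_sits_at_boundary(self):
        # truth sigma_a^2 = 0: REML mass at the boundary approaches 1/2,
        # the rest is small positive noise
        at_zero, ests = 0, []
        for s in range(10):
            cfg = SimulationConfig(n_animals=200, n_snps=500,
                                   traits=[TraitSpec("y", qtl=[], h2=0.0)],
                                   seed=300 + s)
            g = simulate_genotypes(cfg)
            ph = simulate_phenotypes(g, cfg)
            fit = fit_null_model(ph, compute_grm(g), "y")
            at_zero += fit.h2 == 0.0
            ests.append(fit.h2)
        assert at_zero >= 4
        assert np.mean(ests) < 0.15

    def test_single_herd_rejected(self):
        ph = make_pheno(10, {"y": np.zeros(10)})
        df = ph.data.assign(herd="h1")
        with pytest.raises(ValueError, match="herd"):
            fit_null_model(PhenotypeTable(df),
                           identity_grm(df["animal"]), "y")


class TestScan:
    def test_matches_ols_when_no_genetic_variance(self):
        # 12-animal table, G = I and sigma_a ~ 0: GLS per SNP must equal OLS
        rng = np.random.default_rng(22)
        dos = rng.choice([0.0, 1.0, 2.0], size=(12, 6))
        genos = make_genos(dos)
        ph = make_pheno(12, {"y": rng.normal(size=12)}, seed=22)
        grm = identity_grm(genos.samples)
        fit = fit_null_model(ph, grm, "y")
        # exact mode re-estimates the residual variance per SNP, which is
        # what the OLS oracle does; approx mode shares beta but uses the
        # null-model variance in the standard error
        res = scan_snps(ph, grm, genos, "y", mode="exact", null=fit)
        res_approx = scan_snps(ph, grm, genos, "y", null=fit)
        np.testing.assert_allclose(res_approx["beta"], res["beta"], rtol=1e-6)
        X, _ = build_design(ph)
        y = ph.trait("y")
        for j in range(6):
            if res["p"].isna()[j]:
                continue
            Xa = np.column_stack([X, dos[:, j]])
            beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
            resid = y - Xa @ beta
            s2 = resid @ resid / (12 - Xa.shape[1])
            cov = s2 * np.linalg.inv(Xa.T @ Xa)
            assert res["beta"][j] == pytest.approx(beta[-1], rel=1e-6)
            assert res["se"][j] == pytest.approx(np.sqrt(cov[-1, -1]), rel=1e-3)

    def test_monomorphic_snp_flagged_missing(self):
        dos = np.ones((20, 2))
        dos[:, 0] = np.random.default_rng(1).choice([0, 1, 2], 20)
        dos[:, 1] = 2.0
        genos = make_genos(dos)
        ph = make_pheno(20, {"y": np.random.default_rng(2).normal(size=20)})
        res = scan_snps(ph, identity_grm(genos.samples), genos, "y")
        assert np.isnan(res["p"][1])
        assert np.isfinite(res["p"][0])

    def test_missing_dosage_drops_animal_for_that_snp(self, sim_cohort):
        _, genos, pheno = sim_cohort
        grm = compute_grm(genos)
        dos = genos.dosages.copy()
        dos[0, 5] = np.nan
        genos2 = make_genos(dos, chrom=list(genos.variants["chrom"]),
                            pos=list(genos.variants["pos"]),
                            samples=genos.samples)
        null = fit_null_model(pheno, grm, "y")
        res = scan_snps(pheno, grm, genos2, "y", null=null)
        assert res["n_used"][5] == genos.n_samples - 1
        assert np.isfinite(res["p"][5])

    def test_invariant_to_sample_reordering(self, sim_cohort):
        _, genos, pheno = sim_cohort
        grm = compute_grm(genos)
        res = scan_snps(pheno, grm, genos, "y")
        perm = np.random.default_rng(3).permutation(genos.n_samples)
        genos_p = genos.subset(sample_idx=perm)
        pheno_p = PhenotypeTable(
            pheno.data.iloc[perm].reset_index(drop=True))
        grm_p = compute_grm(genos_p)
        res_p = scan_snps(pheno_p, grm_p, genos_p, "y")
        np.testing.assert_allclose(res_p["beta"], res["beta"], rtol=1e-5)
        np.testing.assert_allclose(res_p["p"], res["p"], rtol=1e-4)

    def test_allele_swap_flips_effect_sign_only(self, sim_cohort):
        _, genos, pheno = sim_cohort
        grm = compute_grm(genos)
        res = scan_snps(pheno, grm, genos, "y")
        flipped = genos.flip_alleles(np.arange(10))
        res_f = scan_snps(pheno, grm, flipped, "y")
        np.testing.assert_allclose(res_f["beta"][:10], -res["beta"][:10],
                                   rtol=1e-8)
        np.testing.assert_allclose(res_f["p"][:10], res["p"][:10], rtol=1e-8)

    def test_approx_and_exact_modes_agree(self):
        cfg = SimulationConfig(
            n_animals=200, n_snps=500,
            traits=[TraitSpec("y", qtl=[(250, 0.1)], h2=0.4)], seed=23)
        genos = simulate_genotypes(cfg)
        pheno = simulate_phenotypes(genos, cfg)
        grm = compute_grm(genos)
        null = fit_null_model(pheno, grm, "y")
        res_a = scan_snps(pheno, grm, genos, "y", mode="approx", null=null)
        res_e = scan_snps(pheno, grm, genos, "y", mode="exact", null=null)
        la = -np.log10(res_a["p"].to_numpy())
        le = -np.log10(res_e["p"].to_numpy())
        # the two-stage approximation error grows with the SNP's own effect
        # (variance components absorb a large QTL in the null fit): tight
        # agreement off the major signal, rank agreement at the QTL
        background = le < 3
        assert np.nanmax(np.abs(la - le)[background]) < 0.5
        assert np.corrcoef(la[background], le[background])[0, 1] > 0.99
        assert res_a["p"].idxmin() == res_e["p"].idxmin() == 250


class TestVarianceExplained:
    def test_zero_effect_gives_zero(self):
        assert variance_explained(0.0, 0.3, 1.0) == 0.0

    def test_hand_value(self):
        assert variance_explained(1.0, 0.5, 2.0) == pytest.approx(0.25)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(1.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            variance_explained(1.0, 0.0, 1.0)


class TestQValues:
    def test_bh_equality_on_worked_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        q = compute_qvalues(p, pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_bh(self):
        rng = np.random.default_rng(24)
        p = rng.uniform(size=200)
        q = compute_qvalues(p, pi0=1.0)
        # brute-force BH: q_(i) = min over j>=i of m p_(j) / j
        order = np.argsort(p)
        m = len(p)
        q_bf = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, m * p[order[rank]] / (rank + 1))
            q_bf[order[rank]] = running
        np.testing.assert_allclose(q, q_bf, atol=1e-12)

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(compute_qvalues(np.ones(5)), np.ones(5))

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(25)
        p = rng.uniform(size=500) ** 2
        q = compute_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_qvalues(np.array([]))
        with pytest.raises(ValueError):
            compute_qvalues(np.array([0.0, 0.5]))

    def test_pi0_near_one_under_null(self):
        rng = np.random.default_rng(26)
        p = rng.uniform(size=5000)
        assert estimate_pi0(p) > 0.8

    def test_threshold_in_neglogp_units(self):
        p = np.array([1e-6, 1e-5, 0.5, 0.9])
        q = compute_qvalues(p, pi0=1.0)
        thr = significance_threshold_neglogp(p, q, 0.10)
        assert thr == pytest.approx(-np.log10(1e-5))
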
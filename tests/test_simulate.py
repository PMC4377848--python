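import numpy as np
import pytest

from fagwas.simulate import (SimulationConfig, TraitSpec, paired_configs,
                             share_qtl, simulate_annotation,
                             simulate_genotypes, simulate_phenotypes)


def adjacent_corr(dosages, lag=1):
    """Mean correlation between dosage columns ``lag`` apart."""
    rs = []
    for j in range(dosages.shape[1] - lag):
        a, b = dosages[:, j], dosages[:, j + lag]
        if a.std() > 0 and b.std() > 0:
            rs.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(rs))


class TestGenotypes:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_animals=50, n_snps=100, seed=9)
        g1 = simulate_genotypes(cfg)
        g2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert g1.samples == g2.samples

    def test_breed_label_changes_draw(self):
        cfg = SimulationConfig(n_animals=50, n_snps=100, seed=9)
        g1 = simulate_genotypes(cfg, "breedA")
        g2 = simulate_genotypes(cfg, "breedB")
        assert not np.array_equal(g1.dosages, g2.dosages)

    def test_no_ld_when_rho_zero(self):
        cfg = SimulationConfig(n_animals=400, n_snps=2000, rho=0.0, seed=10)
        g = simulate_genotypes(cfg)
        assert abs(adjacent_corr(g.dosages)) < 0.05

    def test_ld_decays_with_distance(self):
        cfg = SimulationConfig(n_animals=300, n_snps=1000, n_chromosomes=1,
                               rho=0.9, seed=12)
        g = simulate_genotypes(cfg)
        r2_adj = adjacent_corr(g.dosages, lag=1) ** 2
        r2_far = adjacent_corr(g.dosages, lag=50) ** 2
        # thresholding attenuates the latent 0.9, but decay stays monotone
        assert r2_adj > 0.1
        assert r2_adj > 5 * r2_far

    def test_no_monomorphic_loci(self):
        cfg = SimulationConfig(n_animals=100, n_snps=500, seed=13)
        g = simulate_genotypes(cfg)
        assert (g.maf() > 0).all()

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            SimulationConfig(rho=1.0)


class TestPhenotypes:
    def test_residual_only_variance(self):
        # no QTL, no polygenic, fixed effects still present: variance of the
        # residual construction checked against its target on the residual scale
        cfg = SimulationConfig(
            n_animals=400, n_snps=200, herd_sd=0.0,
            parity_effects=(0.0, 0.0, 0.0), dim_slope=0.0,
            traits=[TraitSpec("y", qtl=[], h2=0.0, residual_var=2.0)], seed=14)
        g = simulate_genotypes(cfg)
        ph = simulate_phenotypes(g, cfg)
        assert ph.trait("y").var() == pytest.approx(2.0, rel=0.10)

    def test_planted_qtl_hits_target_r2(self):
        # fixed effects zeroed so the SNP's raw R2 targets the planted 0.2
        r2s = []
        for s in range(20):
            cfg = SimulationConfig(
                n_animals=400, n_snps=300, herd_sd=0.0,
                parity_effects=(0.0, 0.0, 0.0), dim_slope=0.0,
                traits=[TraitSpec("y", qtl=[(100, 0.2)], h2=0.0)], seed=500 + s)
            g = simulate_genotypes(cfg)
            ph = simulate_phenotypes(g, cfg)
            r2s.append(np.corrcoef(g.dosages[:, 100], ph.trait("y"))[0, 1] ** 2)
        assert np.mean(r2s) == pytest.approx(0.2, abs=0.05)

    def test_residual_correlation_realized_between_traits(self):
        cfg = SimulationConfig(
            n_animals=600, n_snps=100, herd_sd=0.0,
            parity_effects=(0.0, 0.0, 0.0), dim_slope=0.0,
            residual_corr=0.5,
            traits=[TraitSpec("a", qtl=[], h2=0.0),
                    TraitSpec("b", qtl=[], h2=0.0)], seed=30)
        g = simulate_genotypes(cfg)
        ph = simulate_phenotypes(g, cfg)
        r = np.corrcoef(ph.trait("a"), ph.trait("b"))[0, 1]
        assert r == pytest.approx(0.5, abs=0.1)

    def test_traits_with_shared_qtl_and_residuals_correlate_higher(self):
        # architecture sharing a QTL and residual component vs an
        # independent trait: the phenotypic correlation separates them
        cfg = SimulationConfig(
            n_animals=400, n_snps=200, residual_corr=0.4,
            traits=[TraitSpec("x", qtl=[(50, 0.2)], h2=0.0),
                    TraitSpec("y", qtl=[(50, 0.2)], h2=0.0)], seed=31)
        g = simulate_genotypes(cfg)
        ph = simulate_phenotypes(g, cfg)
        cfg0 = SimulationConfig(
            n_animals=400, n_snps=200, residual_corr=0.0,
            traits=[TraitSpec("x", qtl=[(50, 0.2)], h2=0.0),
                    TraitSpec("y", qtl=[(120, 0.2)], h2=0.0)], seed=31)
        ph0 = simulate_phenotypes(simulate_genotypes(cfg0), cfg0)
        r_shared = np.corrcoef(ph.trait("x"), ph.trait("y"))[0, 1]
        r_disjoint = np.corrcoef(ph0.trait("x"), ph0.trait("y"))[0, 1]
        assert r_shared > r_disjoint + 0.2

    def test_qtl_at_monomorphic_locus_errors(self):
        cfg = SimulationConfig(
            n_animals=30, n_snps=20,
            traits=[TraitSpec("y", qtl=[(5, 0.1)])], seed=15)
        g = simulate_genotypes(cfg)
        g.dosages[:, 5] = 0.0
        with pytest.raises(ValueError, match="monomorphic"):
            simulate_phenotypes(g, cfg)

    def test_variance_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError, match="fractions"):
            TraitSpec("y", qtl=[(0, 0.5)], h2=0.6)


class TestSharedQtl:
    def test_full_sharing_keeps_indices(self):
        traits = [TraitSpec("y", qtl=[(3, 0.1), (7, 0.05)])]
        out = share_qtl(traits, 1.0, 100, np.random.default_rng(0))
        assert [s for s, _ in out[0].qtl] == [3, 7]

    def test_no_sharing_moves_indices(self):
        traits = [TraitSpec("y", qtl=[(3, 0.1), (7, 0.05)])]
        out = share_qtl(traits, 0.0, 10_000, np.random.default_rng(0))
        assert [s for s, _ in out[0].qtl] != [3, 7]

    def test_paired_configs_follow_two_cohort_design(self):
        base = SimulationConfig(traits=[TraitSpec("y", qtl=[(3, 0.1)])],
                                shared_qtl_fraction=1.0, seed=16)
        c1, c2 = paired_configs(base)
        assert (c1.n_herds, c2.n_herds) == (20, 22)
        assert c1.dim_range == (129, 229)
        assert c2.dim_range == (130, 252)
        assert c1.traits[0].qtl == c2.traits[0].qtl


class TestAnnotation:
    def test_full_fraction_covers_every_snp(self):
        cfg = SimulationConfig(n_animals=20, n_snps=200, seed=17)
        g = simulate_genotypes(cfg)
        genes, _ = simulate_annotation(g, n_genes=20, n_sets=3, seed=17,
                                       fraction_in_genes=1.0)
        covered = np.zeros(g.n_variants, bool)
        for _, gene in genes.data.iterrows():
            on = (g.variants["chrom"] == gene.chrom) & \
                 (g.variants["pos"] >= gene.start) & \
                 (g.variants["pos"] <= gene.end)
            covered |= on.to_numpy()
        assert covered.all()

    def test_causal_set_contains_host_gene(self):
        cfg = SimulationConfig(n_animals=20, n_snps=200, seed=18)
        g = simulate_genotypes(cfg)
        genes, sets = simulate_annotation(g, n_genes=20, n_sets=5, seed=18,
                                          causal_set_snp=42)
        pos = g.variants.iloc[42]
        hosts = genes.data[(genes.data["chrom"] == pos["chrom"]) &
                           (genes.data["start"] <= pos["pos"]) &
                           (genes.data["end"] >= pos["pos"])]
        assert len(hosts) >= 1
        first_set = list(sets.sets.values())[0]
        assert any(h in first_set for h in hosts["gene"])

    def test_zero_sets_gives_empty_collection(self):
        cfg = SimulationConfig(n_animals=20, n_snps=100, seed=19)
        g = simulate_genotypes(cfg)
        _, sets = simulate_annotation(g, n_genes=10, n_sets=0, seed=19)
        assert len(sets) == 0

    def test_gene_intervals_do_not_overlap(self):
        cfg = SimulationConfig(n_animals=20, n_snps=300, seed=20)
        g = simulate_genotypes(cfg)
        genes, _ = simulate_annotation(g, n_genes=30, n_sets=2, seed=20)
        for chrom, sub in genes.data.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] >
                    sub["end"].to_numpy()[:-1]).all()
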
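import numpy as np
import pandas as pd
import pytest

from fagwas.core_io import GenotypeDataset, PhenotypeTable
from fagwas.simulate import SimulationConfig, TraitSpec, simulate_genotypes, simulate_phenotypes


def make_genos(dosages, chrom=None, pos=None, samples=None, a1="A", a2="B"):
    """Small hand-built genotype dataset from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = chrom or ["1"] * m
    pos = pos or list(range(100, 100 + 100 * m, 100))
    samples = samples or [f"s{i}" for i in range(n)]
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "allele1": [a1] * m, "allele2": [a2] * m,
        "id": [f"snp{j}" for j in range(m)],
    })
    return GenotypeDataset(samples, variants, dosages)


def make_pheno(n, traits=None, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "animal": [f"s{i}" for i in range(n)],
        "herd": rng.choice(["h1", "h2", "h3"], size=n),
        "parity": rng.choice([1, 2, 3], size=n),
        "dim": rng.integers(129, 230, size=n),
    })
    for name, vals in (traits or {}).items():
        df[name] = vals
    return PhenotypeTable(df)


@pytest.fixture(scope="session")
def sim_cohort():
    """One simulated cohort with a planted 20%-variance QTL (index 300)."""
    cfg = SimulationConfig(
        n_animals=250, n_snps=1000, n_chromosomes=4,
        traits=[TraitSpec("y", qtl=[(300, 0.2)], h2=0.3),
                TraitSpec("null", qtl=[], h2=0.3)],
        seed=11)
    genos = simulate_genotypes(cfg)
    pheno = simulate_phenotypes(genos, cfg)
    return cfg, genos, pheno
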
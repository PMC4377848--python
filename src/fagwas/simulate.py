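"""Two-breed synthetic data with the structure the analysis assumes.

Genotypes are built from haplotypes generated by a Gaussian-copula first-order
Markov chain along each chromosome: a latent AR(1) process with adjacent
correlation ``rho`` is thresholded at each locus's allele-frequency quantile,
and the dosage is the sum of two independent haplotypes.  This gives
Hardy-Weinberg genotypes with tunable, monotonically decaying LD — enough to
exercise the rotation-permutation tests, without coalescent realism.

Phenotypes follow the association model: herd and parity fixed effects, a
days-in-milk regression, planted additive QTL hitting configured fractions of
the total variance, a polygenic term drawn with covariance proportional to the
realized genomic relationship matrix of the simulated genotypes, and iid
residual noise.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_io import (GeneSetCollection, GeneTable, GenotypeDataset,
                      PhenotypeTable, VARIANT_COLUMNS)
from .grm import compute_grm


@dataclass
class TraitSpec:
    """Architecture of one simulated trait.

    ``qtl`` is a list of (snp index, variance fraction); ``h2`` the polygenic
    variance fraction; ``residual_var`` the residual variance in trait units.
    The total variance implied is residual_var / (1 - h2 - sum fractions).
    """

    name: str
    qtl: list[tuple[int, float]] = field(default_factory=list)
    h2: float = 0.3
    residual_var: float = 1.0

    def __post_init__(self):
        frac = self.h2 + sum(f for _, f in self.qtl)
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"{self.name}: h2 + QTL fractions must be in [0,1)")

    @property
    def total_var(self) -> float:
        return self.residual_var / (1.0 - self.h2 - sum(f for _, f in self.qtl))


@dataclass
class SimulationConfig:
    """Study-design parameters for one breed cohort."""

    n_animals: int = 400
    n_snps: int = 2000
    n_chromosomes: int = 5
    rho: float = 0.35               # adjacent-haplotype latent correlation
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_herds: int = 20
    parity_probs: tuple[float, ...] = (0.45, 0.35, 0.20)
    dim_range: tuple[int, int] = (129, 229)
    herd_sd: float = 0.5
    parity_effects: tuple[float, ...] = (0.0, 0.15, 0.25)
    dim_slope: float = -0.005
    traits: list[TraitSpec] = field(default_factory=list)
    residual_corr: float = 0.0      # exchangeable residual correlation across traits
    shared_qtl_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0,1)")
        if not 0.0 <= self.residual_corr < 1.0:
            raise ValueError("residual_corr must be in [0,1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")


def _breed_rng(seed: int, breed: str, stream: int) -> np.random.Generator:
    tag = zlib.crc32(breed.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed, tag, stream])


def simulate_genotypes(config: SimulationConfig, breed: str = "breed1",
                       max_retries: int = 10) -> GenotypeDataset:
    """Simulate array genotypes for one breed.

    Chromosomes get near-equal numbers of SNPs at 1 kb spacing.  Target
    allele-2 frequencies are drawn so the minor-allele frequency lies in
    ``maf_range``; chromosomes yielding any monomorphic locus are redrawn up
    to ``max_retries`` times before erroring.
    """
    rng = _breed_rng(config.seed, breed, 0)
    n, m, k = config.n_animals, config.n_snps, config.n_chromosomes
    counts = [m // k + (1 if c < m % k else 0) for c in range(k)]
    blocks, meta = [], []
    gidx = 0
    for c, mc in enumerate(counts, start=1):
        for attempt in range(max_retries):
            dos = _simulate_chromosome(rng, n, mc, config)
            maf = np.minimum(dos.mean(axis=0) / 2, 1 - dos.mean(axis=0) / 2)
            if (maf > 0).all():
                break
        else:
            raise RuntimeError(
                f"chromosome {c}: monomorphic loci persisted after "
                f"{max_retries} redraws; MAF range {config.maf_range} unsatisfiable")
        blocks.append(dos)
        for i in range(mc):
            meta.append((str(c), 1000 * (i + 1), "A", "B", f"m{gidx:06d}"))
            gidx += 1
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    return GenotypeDataset([f"{breed}_a{i:04d}" for i in range(n)],
                           variants, np.hstack(blocks))


def _simulate_chromosome(rng, n, mc, config) -> np.ndarray:
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=mc)
    side = rng.integers(0, 2, size=mc)
    p = np.where(side == 1, 1.0 - maf, maf)  # allele-2 frequency
    thresh = norm.ppf(p)
    rho = config.rho
    eps = rng.standard_normal((2 * n, mc))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, mc):
        z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
    haps = (z < thresh).astype(float)
    return haps[:n] + haps[n:]


def simulate_phenotypes(genos: GenotypeDataset, config: SimulationConfig,
                        breed: str = "breed1") -> PhenotypeTable:
    """Simulate trait values on top of simulated genotypes.

    QTL allele-substitution effects are solved from the realized allele
    frequencies so each QTL contributes its configured fraction of the trait's
    total variance; the polygenic term is drawn as N(0, sigma_a^2 G) using the
    realized genomic relationship matrix, so downstream REML recovery targets
    are internally consistent.
    """
    rng = _breed_rng(config.seed, breed, 1)
    n = genos.n_samples
    herd = rng.integers(0, config.n_herds, size=n)
    parity = rng.choice([1, 2, 3], size=n, p=np.asarray(config.parity_probs))
    dim = rng.integers(config.dim_range[0], config.dim_range[1] + 1, size=n)
    herd_effects = rng.normal(0.0, config.herd_sd, size=config.n_herds)
    base = (herd_effects[herd]
            + np.asarray(config.parity_effects)[parity - 1]
            + config.dim_slope * (dim - dim.mean()))

    freqs = genos.allele2_freq()
    grm = compute_grm(genos)
    # one Cholesky shared by all traits of the breed
    L = np.linalg.cholesky(grm.values + 1e-6 * np.eye(n))

    cols = {"animal": genos.samples, "herd": [f"h{h:02d}" for h in herd],
            "parity": parity, "dim": dim}
    # shared residual component inducing an exchangeable correlation of
    # residual_corr between every trait pair (milk FA traits co-vary through
    # shared physiology beyond their shared QTL)
    z_shared = rng.standard_normal(n)
    rc = config.residual_corr
    for spec in config.traits:
        total = spec.total_var
        y = base.copy()
        for snp, frac in spec.qtl:
            p = freqs[snp]
            if p <= 0.0 or p >= 1.0:
                raise ValueError(
                    f"{spec.name}: QTL at monomorphic locus index {snp}")
            b = np.sqrt(frac * total / (2.0 * p * (1.0 - p)))
            g = genos.dosages[:, snp]
            y += b * (g - g.mean())
        if spec.h2 > 0:
            y += L @ rng.standard_normal(n) * np.sqrt(spec.h2 * total)
        eps = (np.sqrt(rc) * z_shared
               + np.sqrt(1.0 - rc) * rng.standard_normal(n))
        y += np.sqrt(spec.residual_var) * eps
        cols[spec.name] = y
    return PhenotypeTable(pd.DataFrame(cols))


def share_qtl(traits: list[TraitSpec], fraction: float, n_snps: int,
              rng: np.random.Generator) -> list[TraitSpec]:
    """Second-breed trait specs sharing a fraction of causal SNP indices.

    The first round(fraction * n_qtl) QTL of each trait keep their SNP index;
    the rest are re-drawn uniformly (avoiding the shared ones).
    """
    out = []
    for spec in traits:
        n_shared = int(round(fraction * len(spec.qtl)))
        kept = spec.qtl[:n_shared]
        taken = {s for s, _ in kept}
        moved = []
        for snp, frac in spec.qtl[n_shared:]:
            new = int(rng.integers(0, n_snps))
            while new in taken:
                new = int(rng.integers(0, n_snps))
            taken.add(new)
            moved.append((new, frac))
        out.append(replace(spec, qtl=kept + moved))
    return out


def paired_configs(base: SimulationConfig,
                   n_animals2: int | None = None) -> tuple[SimulationConfig, SimulationConfig]:
    """Configs for a two-cohort design: 20 vs 22 herds, DIM 129-229 vs 130-252,
    causal SNP indices shared per ``shared_qtl_fraction``."""
    rng = np.random.default_rng([base.seed, 2])
    traits2 = share_qtl(base.traits, base.shared_qtl_fraction, base.n_snps, rng)
    cfg1 = replace(base, n_herds=20, dim_range=(129, 229))
    cfg2 = replace(base, n_herds=22, dim_range=(130, 252), traits=traits2,
                   n_animals=n_animals2 or base.n_animals)
    return cfg1, cfg2


def simulate_annotation(genos: GenotypeDataset, n_genes: int, n_sets: int,
                        seed: int, fraction_in_genes: float = 0.7,
                        set_size_range: tuple[int, int] = (5, 30),
                        causal_set_snp: int | None = None,
                        ) -> tuple[GeneTable, GeneSetCollection]:
    """Tile non-overlapping gene intervals along the simulated chromosomes and
    sample gene sets.

    Genes partition each chromosome's SNPs into consecutive blocks; each gene
    spans the first ``fraction_in_genes`` of its block's SNPs, so that fraction
    of SNPs falls inside genes.  If ``causal_set_snp`` is given, the gene
    hosting that SNP (extended to cover it if needed) is forced into the first
    set.
    """
    rng = np.random.default_rng([seed, 3])
    chroms = list(dict.fromkeys(genos.variants["chrom"]))
    snp_counts = genos.variants["chrom"].value_counts()
    total = genos.n_variants
    rows = []
    gid = 0
    for chrom in chroms:
        sub = genos.variants[genos.variants["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        gc = max(1, int(round(n_genes * snp_counts[chrom] / total)))
        block = len(pos) / gc
        if block < 1:
            raise ValueError(
                f"chromosome {chrom}: {len(pos)} SNPs cannot host {gc} genes")
        for g in range(gc):
            i0 = int(np.floor(g * block))
            i1 = int(np.floor((g + 1) * block)) - 1
            cov = max(i0, i0 + int(np.ceil(fraction_in_genes * (i1 - i0 + 1))) - 1)
            start, end = int(pos[i0]), int(pos[cov])
            if fraction_in_genes >= 1.0 and g == gc - 1:
                end = int(pos[-1])
            rows.append((f"gene{gid:04d}", chrom, start, max(end, start + 1)))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])

    if causal_set_snp is not None:
        vc = genos.variants.iloc[causal_set_snp]
        on_chrom = genes[genes["chrom"] == vc["chrom"]]
        inside = on_chrom[(on_chrom["start"] <= vc["pos"]) & (on_chrom["end"] >= vc["pos"])]
        if len(inside):
            host = inside.index[0]
        else:  # extend the nearest earlier gene on the chromosome to cover it
            before = on_chrom[on_chrom["start"] <= vc["pos"]]
            host = (before.index[-1] if len(before) else on_chrom.index[0])
            genes.loc[host, "start"] = min(genes.loc[host, "start"], int(vc["pos"]) - 1)
            genes.loc[host, "end"] = max(genes.loc[host, "end"], int(vc["pos"]))
        host_gene = genes.loc[host, "gene"]
    else:
        host_gene = None

    sets: dict[str, list[str]] = {}
    gene_ids = genes["gene"].tolist()
    lo, hi = set_size_range
    for s in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(gene_ids))
        members = list(rng.choice(gene_ids, size=size, replace=False))
        if s == 0 and host_gene is not None and host_gene not in members:
            members[0] = host_gene
        sets[f"set{s:03d}"] = members
    return GeneTable(genes), GeneSetCollection(sets) if sets else GeneSetCollection({})
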
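"""VanRaden method-1 genomic relationship matrix.

With dosages coded 0/1/2 copies of allele2, M = dosage - 1 takes values
-1/0/1; P holds columns 2(p_i - 0.5) with p_i the allele-2 frequency; and

    G = Z Z' / [2 sum_i p_i (1 - p_i)],   Z = M - P.

Missing dosages contribute 0 to Z (mean imputation at the Z level), the
standard practice that keeps E[Z] = 0.  Per-chromosome matrices combine into
the whole-genome matrix by weighting with their scale denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenotypeDataset


@dataclass
class GRMatrix:
    samples: list[str]
    values: np.ndarray          # symmetric n x n
    denominator: float          # 2 sum p_i (1 - p_i)
    chromosomes: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("GRM dimension does not match sample list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM is not symmetric")
        if self.denominator <= 0:
            raise ValueError("GRM denominator must be positive")


def compute_grm(genos: GenotypeDataset, chromosomes=None) -> GRMatrix:
    """Whole-genome (default) or chromosome-subset relationship matrix."""
    if chromosomes is not None:
        wanted = set(map(str, chromosomes))
        vi = np.flatnonzero(genos.variants["chrom"].astype(str).isin(wanted))
        if len(vi) == 0:
            raise ValueError(f"no variants on chromosomes {sorted(wanted)}")
        genos = genos.subset(variant_idx=vi)
        chrom_list = sorted(wanted)
    else:
        chrom_list = list(dict.fromkeys(genos.variants["chrom"].astype(str)))
    p = genos.allele2_freq()
    poly = (p > 0) & (p < 1)
    if poly.sum() < 1:
        raise ValueError("all loci monomorphic: cannot compute a GRM")
    denom = float(2.0 * np.sum(p[poly] * (1.0 - p[poly])))
    if denom <= 0:
        raise ValueError("all loci monomorphic: zero GRM denominator")
    M = genos.dosages[:, poly] - 1.0
    Z = M - 2.0 * (p[poly] - 0.5)
    Z[np.isnan(Z)] = 0.0  # mean imputation at the Z level
    return GRMatrix(list(genos.samples), Z @ Z.T / denom, denom, chrom_list)


def per_chromosome_grms(genos: GenotypeDataset) -> list[GRMatrix]:
    chroms = list(dict.fromkeys(genos.variants["chrom"].astype(str)))
    return [compute_grm(genos, [c]) for c in chroms]


def loco_grm(genos: GenotypeDataset, leave_out: str) -> GRMatrix:
    """Leave-one-chromosome-out GRM for association on that chromosome."""
    chroms = [c for c in dict.fromkeys(genos.variants["chrom"].astype(str))
              if c != str(leave_out)]
    if not chroms:
        raise ValueError("cannot leave out the only chromosome")
    return compute_grm(genos, chroms)


def combine_grms(parts: list[GRMatrix]) -> GRMatrix:
    """Denominator-weighted combination, algebraically equal to the
    whole-genome matrix over the union of loci."""
    if not parts:
        raise ValueError("no GRM parts to combine")
    ref = parts[0].samples
    for part in parts[1:]:
        if part.samples != ref:
            raise ValueError("GRM parts cover different sample sets")
    denom = sum(p.denominator for p in parts)
    values = sum(p.values * p.denominator for p in parts) / denom
    chroms = [c for p in parts for c in p.chromosomes]
    return GRMatrix(list(ref), values, denom, chroms)


def write_grm(grm: GRMatrix, path) -> None:
    df = pd.DataFrame(grm.values, index=grm.samples, columns=grm.samples)
    df.to_csv(path, sep="\t", index_label="sample")


def read_grm(path) -> GRMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    vals = (vals + vals.T) / 2.0  # symmetrize away text round-trip noise
    # denominator is not recoverable from the matrix alone; mark as unit scale
    return GRMatrix(list(df.index.astype(str)), vals, 1.0, [])
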
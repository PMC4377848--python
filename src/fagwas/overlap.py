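"""Cross-cohort overlap of significant SNPs, and fold enrichment by cutoff.

Each cohort gets a binary SNP x trait incidence matrix (1 iff the SNP's
association p-value is strictly below the cutoff for that trait, rows in
genome order).  The observed overlap per trait is the inner product of the
two cohorts' columns; its null distribution comes from circularly rotating
one cohort's column by a uniform random offset per replicate, which preserves
the positional clustering of significant SNPs while breaking the cross-cohort
alignment.  The empirical p-value is the fraction of rotations with overlap
greater than or equal to the observed value (one-sided).

Fold enrichment compares the observed count of sub-cutoff p-values per trait
with the N*cutoff expected under uniformity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_CUTOFFS = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5)


@dataclass
class IncidenceMatrix:
    values: np.ndarray       # N SNPs x T traits, uint8, genome order
    traits: list[str]
    markers: list[str]
    cutoff: float

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("incidence entries must be binary")
        if self.values.shape != (len(self.markers), len(self.traits)):
            raise ValueError("incidence shape mismatch")


@dataclass
class OverlapResult:
    trait: str
    observed: int
    n_permutations: int
    pvalue: float
    seed: int | None
    no_hits: bool = False   # flagged when either cohort had zero significant SNPs


def build_incidence(results: dict[str, pd.DataFrame],
                    cutoff: float) -> IncidenceMatrix:
    """Binary indicators of p < cutoff per SNP and trait (strict <)."""
    traits = list(results)
    ref = list(results[traits[0]]["marker"])
    cols = []
    for t in traits:
        df = results[t]
        if list(df["marker"]) != ref:
            raise ValueError(f"trait {t!r} is on a different SNP panel")
        p = df["p"].to_numpy(dtype=float)
        cols.append((p < cutoff).astype(np.uint8))  # NaN compares False
    return IncidenceMatrix(np.column_stack(cols), traits, ref, cutoff)


def overlap_test(mA: IncidenceMatrix, mB: IncidenceMatrix,
                 n_permutations: int = 1000, seed: int | None = None,
                 exhaustive: bool = False) -> list[OverlapResult]:
    """Per-trait overlap count and rotation-null empirical p-value."""
    if mA.traits != mB.traits:
        raise ValueError("incidence matrices cover different traits")
    if mA.markers != mB.markers:
        raise ValueError("incidence matrices are on different SNP panels")
    N = len(mA.markers)
    if exhaustive:
        offsets = np.arange(N)
    else:
        if seed is None:
            raise ValueError("a seed is required for a sampled permutation run")
        rng = np.random.default_rng(seed)
    results = []
    for k, trait in enumerate(mA.traits):
        a = mA.values[:, k].astype(np.int64)
        b = mB.values[:, k].astype(np.int64)
        observed = int(a @ b)
        if a.sum() == 0 or b.sum() == 0:
            results.append(OverlapResult(trait, observed,
                                         0, 1.0, seed, no_hits=True))
            continue
        if not exhaustive:
            offsets = rng.integers(0, N, size=n_permutations)
        idx_b = np.flatnonzero(b)
        # rotating a by offset o aligns a[(i - o) mod N] with b[i]
        nulls = a[(idx_b[:, None] - offsets[None, :]) % N].sum(axis=0)
        p = float(np.mean(nulls >= observed))
        results.append(OverlapResult(trait, observed, len(offsets), p, seed))
    return results


def overlap_results_frame(results: list[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.trait, r.observed, r.n_permutations, r.pvalue, r.no_hits)
         for r in results],
        columns=["trait", "overlap", "B", "p", "no_hits"])


def fold_enrichment(results: dict[str, pd.DataFrame],
                    cutoffs=DEFAULT_CUTOFFS,
                    n_snps: int | None = None) -> pd.DataFrame:
    """Observed / expected counts of sub-cutoff p-values per trait and cutoff."""
    rows = []
    for trait, df in results.items():
        p = df["p"].to_numpy(dtype=float)
        N = n_snps or len(p)
        for c in cutoffs:
            if not 0.0 < c < 1.0:
                raise ValueError(f"cutoff {c} outside (0,1)")
            expected = N * c
            if expected < 1:
                log.warning("trait %s cutoff %g: expected count %.3g < 1",
                            trait, c, expected)
            observed = int(np.sum(p < c))
            rows.append((trait, c, observed, expected, observed / expected))
    return pd.DataFrame(rows, columns=["trait", "cutoff", "observed",
                                       "expected", "fold"])
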
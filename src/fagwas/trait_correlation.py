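"""Between-trait correlation matrices from per-SNP t-values.

The Pearson correlation between two traits' signed t-value vectors over the
shared SNP panel is a fast marker-based proxy for the genetic correlation;
comparing the lower triangles of two cohorts' matrices ("correlation of
correlations") summarizes how similar their genetic architectures are.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def tvalue_correlations(results: dict[str, pd.DataFrame],
                        min_shared: int = 10) -> pd.DataFrame:
    """Pearson correlations between traits' t-values over common SNPs.

    ``results`` maps trait name -> association frame (columns marker,
    allele1, allele2, t).  SNP panels are intersected on marker ID; when the
    effect-allele orientation (allele2) differs between tables, the t sign is
    flipped to harmonize.
    """
    traits = list(results)
    if len(traits) < 2:
        raise ValueError("need >=2 traits to correlate")
    ref = results[traits[0]].set_index("marker")
    shared = ref.index
    for t in traits[1:]:
        shared = shared.intersection(results[t].set_index("marker").index)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared SNPs (<{min_shared})")
    shared = list(shared)
    tmat = np.empty((len(shared), len(traits)))
    ref_a2 = ref.loc[shared, "allele2"]
    for k, t in enumerate(traits):
        df = results[t].set_index("marker").loc[shared]
        sign = np.where(df["allele2"].to_numpy() == ref_a2.to_numpy(), 1.0, -1.0)
        tmat[:, k] = df["t"].to_numpy() * sign
    keep = ~np.isnan(tmat).any(axis=1)
    corr = np.corrcoef(tmat[keep].T)
    return pd.DataFrame(corr, index=traits, columns=traits)


def correlation_of_correlations(mA: pd.DataFrame, mB: pd.DataFrame
                                ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation over strictly-lower-triangle entries of two
    trait-correlation matrices, plus the paired scatter table."""
    if list(mA.index) != list(mB.index) or list(mA.columns) != list(mB.columns):
        diff = set(mA.index).symmetric_difference(mB.index)
        raise ValueError(f"trait sets differ: {sorted(diff)}")
    traits = list(mA.index)
    rows = []
    for i in range(1, len(traits)):
        for j in range(i):
            rows.append((traits[i], traits[j],
                         float(mA.iloc[i, j]), float(mB.iloc[i, j])))
    pairs = pd.DataFrame(rows, columns=["trait_row", "trait_col",
                                        "corr_A", "corr_B"])
    if len(pairs) < 2:
        raise ValueError("need >=3 traits for a correlation of correlations")
    r = float(np.corrcoef(pairs["corr_A"], pairs["corr_B"])[0, 1])
    return r, pairs
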
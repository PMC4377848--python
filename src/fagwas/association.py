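"""Single-SNP linear mixed-model association scan.

Model, per trait and cohort:

    y = mu + herd + parity + b1 * DIM + b2 * SNP + u + e,
    u ~ N(0, sigma_a^2 G),   e ~ N(0, sigma_e^2 I)

Variance components come from REML on the null model (no SNP), maximized over
the heritability ratio after rotating the data by the eigenvectors of G, so
the covariance is diagonal and the profile likelihood is one-dimensional.
The default scan mode holds the components fixed from the null fit and
estimates each SNP's allele-substitution effect by generalized least squares
(the standard two-stage approximation); ``mode='exact'`` re-maximizes REML
per SNP for validation.  Each SNP is tested by the Wald statistic
(b2/se)^2 against chi-square(1); the signed t = b2/se is retained for the
trait-correlation and SNP-set stages.

Multiple testing uses Storey q-values: pi0 from the smoother method on a
lambda grid, times Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.interpolate import UnivariateSpline
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .core_io import GenotypeDataset, PhenotypeTable
from .grm import GRMatrix

log = logging.getLogger(__name__)

RIDGE = 1e-6  # jitter added to G's eigenvalues against numerical indefiniteness


@dataclass
class NullModelFit:
    trait: str
    beta: pd.Series              # fixed effects at the optimum
    sigma2_a: float
    sigma2_e: float
    h2: float                    # sigma2_a / (sigma2_a + sigma2_e)
    loglik: float                # restricted log-likelihood
    eigvals: np.ndarray          # eigenvalues of G (ridged)
    eigvecs: np.ndarray
    X: np.ndarray                # fixed-effect design (original space)
    y: np.ndarray
    samples: list[str]

    @property
    def total_var(self) -> float:
        return self.sigma2_a + self.sigma2_e


def build_design(pheno: PhenotypeTable) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded herd and parity dummies + centred DIM."""
    df = pheno.data
    herd = pd.get_dummies(df["herd"].astype(str), prefix="herd", drop_first=True)
    parity = pd.get_dummies(df["parity"].astype(int), prefix="parity", drop_first=True)
    dim = df["dim"].to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(df)),
        herd.to_numpy(dtype=float),
        parity.to_numpy(dtype=float),
        dim - dim.mean(),
    ])
    names = ["intercept", *herd.columns, *parity.columns, "dim"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    return X, names


def _align(pheno: PhenotypeTable, grm: GRMatrix):
    ids = list(pheno.data["animal"].astype(str))
    if ids != list(grm.samples):
        pos = {s: i for i, s in enumerate(grm.samples)}
        try:
            idx = [pos[a] for a in ids]
        except KeyError as e:
            raise ValueError(f"animal {e} missing from GRM") from None
        G = grm.values[np.ix_(idx, idx)]
    else:
        G = grm.values
    return G


def _reml_neg2(h2: float, S: np.ndarray, Xr: np.ndarray, yr: np.ndarray) -> float:
    """-2 x restricted log-likelihood, profiled over sigma_e^2, at ratio h2."""
    h2 = min(max(h2, 0.0), 1.0 - 1e-9)
    delta = h2 / (1.0 - h2)
    d = delta * S + 1.0
    w = 1.0 / d
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    c, low = cho_factor(XtWX)
    beta = cho_solve((c, low), XtWy)
    r = yr - Xr @ beta
    n, p = Xr.shape
    rss = float(np.sum(r * r * w))
    sigma2e = rss / (n - p)
    logdet_XtWX = 2.0 * np.sum(np.log(np.diag(c)))
    return ((n - p) * np.log(2.0 * np.pi * sigma2e) + np.sum(np.log(d))
            + logdet_XtWX + (n - p))


def fit_null_model(pheno: PhenotypeTable, grm: GRMatrix, trait: str,
                   n_grid: int = 50) -> NullModelFit:
    """REML fit of the no-SNP model via the eigendecomposition of G.

    A grid over h2 in [0, 0.99] locates the basin; bounded 1-D minimization
    refines it.  A boundary estimate (sigma_a^2 = 0) is allowed with a warning.
    """
    if pheno.data["herd"].nunique() < 2:
        raise ValueError("need >=2 herd levels to fit the null model")
    G = _align(pheno, grm)
    y = pheno.trait(trait)
    keep = ~np.isnan(y)
    if not keep.all():
        pheno = PhenotypeTable(pheno.data.loc[keep].reset_index(drop=True))
        G = G[np.ix_(keep.nonzero()[0], keep.nonzero()[0])]
        y = y[keep]
    X, names = build_design(pheno)
    S, U = np.linalg.eigh(G)
    S = np.maximum(S, 0.0) + RIDGE
    yr, Xr = U.T @ y, U.T @ X

    grid = np.linspace(0.0, 0.99, n_grid)
    vals = [_reml_neg2(h, S, Xr, yr) for h in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(_reml_neg2, bounds=(lo, hi), method="bounded",
                                   args=(S, Xr, yr))
    if not res.success:
        raise RuntimeError(
            f"REML did not converge for {trait!r}; grid trace: "
            + ", ".join(f"{h:.2f}:{v:.2f}" for h, v in zip(grid[::10], vals[::10])))
    h2 = float(res.x) if res.fun <= vals[i] else float(grid[i])
    if h2 < 1e-4:
        h2 = 0.0
        log.warning("%s: additive variance estimated at the zero boundary", trait)

    delta = h2 / (1.0 - h2)
    d = delta * S + 1.0
    w = 1.0 / d
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    r = yr - Xr @ beta
    n, p = Xr.shape
    sigma2e = float(np.sum(r * r * w) / (n - p))
    sigma2a = delta * sigma2e
    return NullModelFit(
        trait=trait, beta=pd.Series(beta, index=names),
        sigma2_a=sigma2a, sigma2_e=sigma2e, h2=h2,
        loglik=-0.5 * _reml_neg2(h2, S, Xr, yr),
        eigvals=S, eigvecs=U, X=X, y=y,
        samples=list(pheno.data["animal"].astype(str)),
    )


def scan_snps(pheno: PhenotypeTable, grm: GRMatrix, genos: GenotypeDataset,
              trait: str, mode: str = "approx",
              null: NullModelFit | None = None) -> pd.DataFrame:
    """Per-SNP allele-substitution estimates, Wald tests and variance explained.

    Returns a frame with columns marker, chrom, pos, allele1, allele2, freq2,
    n_used, beta, se, t, p, var_explained.  Monomorphic SNPs are flagged with
    missing statistics.  Animals with a missing dosage are dropped for that
    SNP only.
    """
    if mode not in ("approx", "exact"):
        raise ValueError("mode must be 'approx' or 'exact'")
    if list(pheno.data["animal"].astype(str)) != list(genos.samples):
        raise ValueError("phenotype and genotype sample orders differ")
    if null is None or null.trait != trait:
        null = fit_null_model(pheno, grm, trait)
    if null.samples != list(genos.samples):
        # trait-missing animals were dropped inside the null fit
        keep = [i for i, s in enumerate(genos.samples) if s in set(null.samples)]
        genos = genos.subset(sample_idx=keep)

    S, U = null.eigvals, null.eigvecs
    X, y = null.X, null.y
    n, p = X.shape
    delta = null.h2 / (1.0 - null.h2) if null.h2 < 1.0 else np.inf
    w = 1.0 / (delta * S + 1.0)
    yr, Xr = U.T @ y, U.T @ X

    dosages = genos.dosages
    freqs = genos.allele2_freq()
    m = genos.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    complete = ~np.isnan(dosages).any(axis=0)
    mono = (freqs <= 0.0) | (freqs >= 1.0)
    if mono.any():
        log.info("%s: %d monomorphic SNP(s) flagged", trait, int(mono.sum()))

    if mode == "approx":
        fast = complete & ~mono
        if fast.any():
            Gr = U.T @ dosages[:, fast]
            Xw = Xr * w[:, None]
            XtWX_inv = np.linalg.inv(Xr.T @ Xw)
            XtWy = Xw.T @ yr
            GtW = Gr * w[:, None]
            gWy = GtW.T @ yr                       # (m,)
            gWX = GtW.T @ Xr                       # (m, p)
            gWg = np.einsum("ij,ij->j", Gr, GtW)   # (m,)
            A = gWX @ XtWX_inv
            gPy = gWy - A @ XtWy
            gPg = gWg - np.einsum("ij,ij->i", A, gWX)
            ok = gPg > 1e-12
            b = np.where(ok, gPy / np.where(ok, gPg, 1.0), np.nan)
            s = np.where(ok, np.sqrt(null.sigma2_e / np.where(ok, gPg, 1.0)), np.nan)
            beta[fast], se[fast] = b, s
        slow = ~complete & ~mono
        for j in np.flatnonzero(slow):
            beta[j], se[j] = _gls_with_missing(
                null, X, y, dosages[:, j])
    else:
        for j in np.flatnonzero(~mono):
            beta[j], se[j] = _exact_snp(null, Xr, yr, U, dosages[:, j], X, y)

    t = beta / se
    pvals = chi2.sf(t**2, df=1)
    n_used = np.sum(~np.isnan(dosages), axis=0)
    with np.errstate(invalid="ignore"):
        varexp = np.clip(
            2.0 * freqs * (1.0 - freqs) * beta**2 / null.total_var, 0.0, 1.0)
    out = genos.variants[["id", "chrom", "pos", "allele1", "allele2"]].copy()
    out = out.rename(columns={"id": "marker"})
    out["freq2"] = freqs
    out["n_used"] = n_used
    out["beta"] = beta
    out["se"] = se
    out["t"] = t
    out["p"] = pvals
    out["var_explained"] = varexp
    out["trait"] = trait
    return out


def _gls_with_missing(null: NullModelFit, X, y, g):
    """GLS for one SNP dropping animals with a missing dosage.

    V is rebuilt in the original space on the retained animals (the rotated
    space is not valid after subsetting)."""
    keep = ~np.isnan(g)
    G_full = (null.eigvecs * null.eigvals) @ null.eigvecs.T
    V = null.sigma2_a * G_full[np.ix_(keep.nonzero()[0], keep.nonzero()[0])] \
        + null.sigma2_e * np.eye(int(keep.sum()))
    Xa = np.column_stack([X[keep], g[keep]])
    c, low = cho_factor(V)
    Vi_X = cho_solve((c, low), Xa)
    XtViX = Xa.T @ Vi_X
    cov = np.linalg.inv(XtViX)
    bhat = cov @ (Vi_X.T @ y[keep])
    return bhat[-1], np.sqrt(cov[-1, -1])


def _exact_snp(null, Xr, yr, U, g, X, y):
    """Re-maximize REML with the SNP in the fixed effects."""
    if np.isnan(g).any():
        return _gls_with_missing(null, X, y, g)  # subset refit out of scope
    Xa = np.column_stack([Xr, U.T @ g])
    res = optimize.minimize_scalar(_reml_neg2, bounds=(0.0, 0.99),
                                   method="bounded", args=(null.eigvals, Xa, yr))
    h2 = float(res.x)
    delta = h2 / (1.0 - h2)
    w = 1.0 / (delta * null.eigvals + 1.0)
    Xw = Xa * w[:, None]
    XtWX = Xa.T @ Xw
    cov = np.linalg.inv(XtWX)
    bhat = cov @ (Xw.T @ yr)
    r = yr - Xa @ bhat
    n, p = Xa.shape
    sigma2e = float(np.sum(r * r * w) / (n - p))
    return bhat[-1], float(np.sqrt(sigma2e * cov[-1, -1]))


def variance_explained(b2: float, p: float, total_var: float) -> float:
    """Fraction of total variance from one SNP: 2 p (1-p) b2^2 / total."""
    if total_var <= 0:
        raise ValueError("total variance must be positive")
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must be in (0,1)")
    return float(np.clip(2.0 * p * (1.0 - p) * b2**2 / total_var, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Storey q-values


def estimate_pi0(pvalues: np.ndarray,
                 lambdas: np.ndarray | None = None) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a grid, cubic smoothing
    spline, evaluated at the largest lambda; clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if p.size < 100:
        return 1.0  # too few tests for a stable smoother
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    spline = UnivariateSpline(lambdas, pi0_l, k=3)
    pi0 = float(spline(lambdas[-1]))
    return float(min(max(pi0, 1e-8), 1.0))


def compute_qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: pi0 times the Benjamini-Hochberg adjusted p-values.

    ``pi0=None`` estimates pi0 by the smoother; ``pi0=1`` reduces exactly to
    Benjamini-Hochberg.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    q_bh = multipletests(p, method="fdr_bh")[1]
    return np.minimum(pi0 * q_bh, 1.0)


def significance_threshold_neglogp(pvalues, qvalues, level: float = 0.10) -> float:
    """-log10 of the largest p-value called significant at q < level.

    Reported for comparability with fixed -log10(P) thresholds; NaN when
    nothing is significant.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.asarray(qvalues, dtype=float)
    sig = q < level
    if not sig.any():
        return float("nan")
    return float(-np.log10(p[sig].max()))
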
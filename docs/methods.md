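# Methods

This note records the statistical model, the choices behind the synthetic
data, and the numerical decisions, in enough detail to audit any number the
package produces.

## Mixed-model association scan

Each trait is analysed per cohort with

y = X beta + g beta_snp + u + e,  u ~ N(0, sigma_a^2 G),  e ~ N(0, sigma_e^2 I),

where X holds an intercept, herd and parity dummies (reference-level coded)
and days in milk (DIM, centred before regression for conditioning), g is the
0/1/2 dosage of the tested SNP, and G is the VanRaden method-1 genomic
relationship matrix.

**GRM.** With dosages counting copies of allele 2, M = dosage − 1 ∈ {−1,0,1},
P's column i is 2(p_i − 0.5) with p_i estimated from non-missing dosages, and
G = ZZ′/[2Σp_i(1−p_i)] with Z = M − P. A missing dosage contributes 0 to Z —
mean imputation at the Z level, the standard practice that keeps E[Z] = 0.
Per-chromosome matrices combine exactly into the whole-genome matrix by
weighting with their denominators; leave-one-chromosome-out construction is
available, but the default scan uses the whole-genome G (a single random
animal effect).

**REML.** The null model (no SNP) is maximized over the heritability ratio
h² = sigma_a²/(sigma_a²+sigma_e²) after rotating y and X by the eigenvectors
of G, which diagonalizes the covariance and makes the restricted likelihood a
one-dimensional profile. A 50-point grid on [0, 0.99] locates the basin and
bounded scalar minimization refines it; eigenvalues receive a ridge of 1e−6
against numerical indefiniteness. A boundary estimate (sigma_a² = 0) is legal
and logged. Under a true zero component the estimate sits exactly at the
boundary roughly half the time (the classical half-mixture), with the rest
small positive noise; with a few hundred near-unrelated animals the sampling
sd of ĥ² is large (≈0.16 at n = 400, m = 2,000) although the estimator is
essentially unbiased — tests therefore check mean bias, not per-replicate
bands.

**Scan.** The default mode fixes the variance components from the null fit
and computes each SNP's allele-substitution estimate by GLS (the two-stage
approximation); `exact` mode re-maximizes REML per SNP. The approximation
error on −log10 p grows with the SNP's own effect, because the null-model
components absorb a large QTL: background SNPs agree to ≲0.1–0.5 while a
20%-variance locus can differ by ~1 −log10 unit, with the ranking preserved.
The Wald statistic (b̂/se)² is referred to chi-square(1); the signed
t = b̂/se feeds the correlation and SNP-set stages. Animals missing a dosage
are dropped for that SNP only (the covariance is then re-solved in the
original space, since the rotated space is invalid after subsetting);
monomorphic SNPs are flagged with missing statistics. The per-SNP variance
contribution is reported as 2p(1−p)b̂²/(sigma_a²+sigma_e²) — "total variance"
here means the genetic-plus-residual variance of the null model; this is the
package's convention and is recorded with the results.

**Multiple testing.** Storey q-values: pi0 is estimated by the smoother
method (pi0(lambda) = #{p > lambda}/(m(1−lambda)) on lambda = 0.05…0.95 step
0.05, cubic smoothing spline evaluated at 0.95, clipped to (0,1]; pi0 := 1
below 100 tests, where the smoother is unstable), then q = min(pi0 × BH, 1).
pi0 = 1 reproduces Benjamini–Hochberg exactly. Significance is declared at
q < 0.10, and the implied −log10 p threshold is reported alongside for
comparison with fixed-threshold studies.

## Trait correlations

The "genetic correlation" proxy between two traits is the Pearson correlation
of their signed t-vectors over the SNP panel shared by marker ID, after
flipping signs where the effect allele differs between tables. Pearson (not
rank) correlation is used. The cross-cohort summary is the Pearson
correlation over strictly-lower-triangle entries of the two cohorts'
matrices. All post-QC SNPs enter; no significance filtering is applied first.

## Circular-permutation SNP-set test

SNPs are assigned to genes by position (inclusive interval, same chromosome)
and to a set at most once via the union of its member genes. The set
statistic is Σ −log10 p over member SNPs — a burden-style score aimed at many
small-to-moderate effects. The base of the logarithm is immaterial: rank
order among rotations, and hence the empirical p, is invariant to it.

The null rotates the genome-ordered statistic vector by a uniformly random
offset (element j becomes first; the gene mapping stays fixed), preserving
neighbouring-statistic correlation induced by LD while breaking SNP–gene
links. The vector rotates genome-wide across chromosome boundaries. All sets
are scored on the same rotations. Default 10,000 rotations, with p =
(#{null ≥ observed} + 1)/(B + 1): ties count as exceeding and zero p-values
are impossible, which makes the test valid at any B. A literal mode
(#{null > observed}/B, ties not exceeding) is available for replication
fidelity; the two differ by at most ~1/B plus the tie mass. Exhaustive
enumeration of all N rotations is exposed and serves as the oracle for the
sampled mode in tests. Sampled runs refuse to start without a seed.

## Cross-cohort overlap and fold enrichment

Incidence matrices are binary SNP × trait indicators of p strictly below the
cutoff (default 1e−4; missing p never significant). Observed overlap per
trait is the inner product of the two cohorts' columns. The null rotates one
cohort's column by a uniform offset, independently per trait and replicate
(rotating both adds nothing under a relative-offset null); default 1,000
rotations with p = #{null ≥ observed}/B — this section's counting is
deliberately "greater or equal", unlike the pathway test's strict ">", and
the asymmetry is kept rather than harmonized because each mirrors its own
test's definition. Zero significant SNPs in either cohort yields p = 1 with
a flag. Fold enrichment is observed/(N·cutoff) per trait over the ladder
{1e−1 … 1e−5}; the exact ladder is configurable since only the 1e−4 point is
canonical. Expected counts below 1 are reported with a warning.

## Quality control

Filter order: sample call rate ≥ 0.80 → locus call rate ≥ 0.95 (recomputed on
retained samples) → per-sample mean genotyping quality ≥ 0.65 (skipped with a
notice when no quality channel exists, as in synthetic data) → MAF ≥ 0.01.
All thresholds are strict "below is removed", so boundary values are kept.
The order is a package decision — locus statistics then reflect retained
samples; MAF is computed after sample exclusions.

## Synthetic data

The generator emulates the study design the analysis assumes: two cohorts
(defaults 20 and 22 herds; DIM ranges 129–229 and 130–252; parities 1–3 with
probabilities 0.45/0.35/0.20), array-like genotypes with local LD, and traits
with planted QTL (the bundled demo plants a 20%-variance major locus and a
20% desaturase-like locus, plus a 7.8% shared effect on a third trait).

- **Genotypes.** Haplotypes come from a Gaussian-copula first-order Markov
  chain per chromosome: a latent AR(1) with adjacent correlation rho is
  thresholded at each locus's allele-frequency quantile; dosage = sum of two
  independent haplotypes. This gives Hardy–Weinberg genotypes and monotone,
  tunable LD decay. Default rho = 0.35 (moderate LD at array density); the
  real-data LD level is not identifiable from published summaries, so rho is
  documented as a free parameter. Thresholding attenuates the latent
  correlation, so realized adjacent dosage r² is well below rho². Target
  allele frequencies draw MAF from U(0.05, 0.5); chromosomes with a
  monomorphic column are redrawn (bounded retries), and realized MAF scatters
  around its target rather than being truncated to the range.
- **Phenotypes.** Herd effects N(0, 0.5²), parity effects (0, 0.15, 0.25),
  DIM slope −0.005/d on centred DIM, all in trait units. QTL
  allele-substitution effects are solved from realized allele frequencies so
  each QTL hits its configured fraction of the trait's total variance; the
  polygenic term is drawn N(0, sigma_a² G) from the realized GRM of the
  simulated genotypes (not an independent pedigree), making REML recovery
  targets internally consistent. Residuals are unit-variance by default with
  an optional exchangeable cross-trait correlation (0.3 in the demo) —
  milk-FA traits co-vary through shared physiology beyond shared QTL, and
  without it marker-based trait correlations on synthetic data are pure
  noise. Variance accounting: with residual variance s², h² and QTL
  fractions f, the implied total is s²/(1 − h² − Σf).
- **Cohort pairing.** The two cohorts are generated independently (separate
  haplotype frequency draws) and share only causal SNP indices, per
  `shared_qtl_fraction` (1 = same causal variants in both breeds).
- **Annotation.** Non-overlapping gene intervals tile each chromosome so a
  configurable fraction of SNPs (default 0.7) falls inside genes; sets sample
  genes without replacement, and a designated causal set can be forced to
  contain the gene hosting a planted QTL.

What passing tests on these data do *not* show: robustness to population
structure or admixture, pedigree relatedness, genotyping error, coalescent
LD patterns, selection, or lactation-curve dynamics — none of which the
generator produces.

## Problem sizes and runtime choices

Tests and the acceptance script run at desk scale: calibration scans at
n = 300, m = 2,000; recovery studies over 10–20 replicates; permutation
oracles at N ≤ 1,000 exhaustive vs B ≤ 5,000 sampled; the bundled pipeline at
2 × 200 animals × 2,000 SNPs with 2,000/500 permutations. These sizes are the
package's fixture choices; all statistics scale to array-sized panels since
every stage is vectorized (the scan's per-SNP cost is O(n) after one
eigendecomposition).

## Known limitations

- Approx-mode standard errors use the null-model residual variance; exact
  mode exists but is O(REML) per SNP.
- The coordinate system assumes one consistent assembly for SNPs and genes;
  lift-over between assemblies is out of scope.
- PLINK text input assigns alleles alphabetically (the dialect carries no
  ref/alt); VCF preserves orientation exactly.
- The pathway test is self-contained (rotation null), not a competitive test
  adjusting for set size or LD beyond what rotation preserves.
- No binary PLINK, imputation, Hardy–Weinberg filtering, dominance, GxE, or
  multi-SNP models.
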
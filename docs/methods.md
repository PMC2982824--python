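# Methods

## Model and tests

Both tests are ordinary least-squares t-tests of a candidate SNP's
additive effect β_s on a quantitative phenotype, with genotypes coded as
minor-allele counts (0/1/2). The multi-locus test (MLT) includes the
confirmed SNPs as fixed covariates; the single-locus test (SLT) omits
them. The package assumes unrelated samples and fits by OLS throughout;
generalized-least-squares handling of family structure, logistic models
for binary traits, epistasis, and genotype imputation are out of scope.

## Power theory

Under Hardy–Weinberg equilibrium the variance of the genotype code is
2pq, and under linkage equilibrium the large-sample value of the
candidate's diagonal element of (X'X)⁻¹ is c = 1/(N·2pq). The MLT
statistic is noncentral-t with df = N − M (M = 1 + p + S) and
noncentrality λ = β_s/√(σ²c); one-sided power is P(T > t_α).

For the SLT, the omitted confirmed effects inflate the residual variance
to σ*² = σ² + Σ β_j²·2p_j q_j (the confirmed SNPs are assumed mutually
independent). Because the SLT's *estimated* residual variance converges
to σ*², its realized rejection threshold is the central-t quantile scaled
by √(σ*²/σ²), applied to a statistic whose noncentrality is still written
on the σ² scale: power = P(T_{λ, N−p−2} > t_α·√(σ*²/σ²)).

A numerical note on this formulation: the exact sampling distribution of
the SLT statistic is noncentral-t with noncentrality λ* = λ/√(σ*²/σ²);
the scaled-threshold expression rescales the threshold instead of the
noncentrality. The two agree to first order in (√(σ*²/σ²) − 1) and differ
by ≲ 0.006 in power at the inflation levels used in the validation
studies here (omitted effects ≤ 0.3 SD), which is inside the Monte-Carlo
tolerance at 2000 replicates. At large inflation (omitted effects near
1 SD) the scaled-threshold form is the one tabulated and reported.

Defaults: σ = 1 (effects in residual-SD units), α = 0.025 one-sided.
The one-sided α = 0.025 convention is the one-sided counterpart of the
conventional two-sided 0.05 and is what the reference power tables here
use; both α and sidedness are explicit parameters everywhere. Two-sided
power is computed as P(|T| > t_{α/2}·scale) and is provided as an
extension: the analytic theory is derived one-sided, and data scans
default to two-sided p-values (the GWAS reporting convention). These two
defaults are independent and deliberate.

`coefficient_variance` offers the closed-form expectation (default,
deterministic) and a realized-design mode that evaluates (X'X)⁻¹ on a
supplied matrix; they agree to O(1/√N) and the tests check the closed
form against the Monte-Carlo mean of realized values.

## Simulation design

The generator emulates the sampling model of the power theory: unlinked
biallelic SNPs with minor-allele counts Binomial(2, maf), phenotype =
mean + additive effects + N(0, σ²) noise. The default validation design
is 2000 subjects, three SNPs with mafs 0.3/0.4/0.2, confirmed effects
0.3 and 0.2 SD, candidate effect 0.1 SD. Empirical power is the
rejection proportion; its Monte-Carlo SE is √(p̂(1−p̂)/n_reps).
Replicates redraw both genotypes and phenotypes, each from a
counter-based stream seeded by (master seed, replicate index), so runs
are bit-reproducible and replicates are individually re-derivable.
Monomorphic draws trigger a replicate redraw (vanishingly rare at the
default mafs and sample sizes) and are counted in the estimate's
diagnostics. Validation suites use 2000 replicates rather than very
large counts, with tolerances expressed in Monte-Carlo SEs, which keeps
the full suite under a few minutes on one core.

What passing these simulations does *not* show: robustness to linkage
disequilibrium between candidate and confirmed SNPs, to population
structure, to relatedness, or to non-normal residuals — none of which
the generator produces. On real data those features are handled only
insofar as covariates, LD pruning of the confirmed set, and Box-Cox
transformation address them.

## Scan engine

Designs are built with columns (intercept, covariates, conditional
genotypes, candidate genotype), so the candidate coefficient is always
last. Samples with any missing value among the columns a test uses are
dropped per test (complete case, no imputation); consequently the MLT
and SLT sample sizes for the same SNP can differ, and `n_used` is
reported per result. A confirmed SNP itself is tested conditional on the
*other* confirmed SNPs (leave-one-out). Rank deficiency is declared at a
reciprocal-condition cutoff of 1e-10 on X'X and reported with the
near-collinear column pairs; per-SNP failures during a scan are recorded
and skipped, not fatal. Covariates must be numerically encoded by the
caller.

## Data preparation

LD pruning is greedy by descending |effect| (ties by position, then
label): a SNP is kept iff its r² — squared Pearson correlation of
genotype codes over shared complete cases — with every already-kept SNP
within the window is below the threshold. "High LD region" has no
universal definition; the defaults r² ≥ 0.8 within 1 Mb are conventional
and both are configurable. Box-Cox selection maximizes the profile
log-likelihood (scipy's `boxcox_llf`) over a user grid and returns the
whole profile so "approximately log" is an observable statement, not a
hard-coded choice.

## File formats

Minor-allele orientation is recomputed from the observed data in every
reader — the model is written in minor-allele copies, and REF/ALT (or
the `.raw` counted allele) need not be the minor allele; a tie at
frequency 0.5 resolves to ALT. VCF reading uses cyvcf2 (GT only;
non-biallelic sites are skipped with a warning); the VCF writer emits a
minimal GT-only v4.2 file with the minor allele as ALT. The `.raw`
dialect carries no coordinates, so scans needing positions require the
sidecar map (snp, chrom, 1-based pos). Phenotype/covariate tables and
all results are tab-separated text; output files begin with `#`
provenance lines (version, config hash, seed).

## Known limitations

- The SLT power formula is the scaled-threshold approximation discussed
  above; its small bias relative to the exact noncentral-t form grows
  with the inflation factor.
- The closed-form coefficient variance assumes linkage equilibrium
  between the candidate and the confirmed set; under real LD the MLT
  loses power relative to these predictions (the realized-design mode
  can quantify this on a given design).
- The conditional scan refits the full model per SNP; it is intended for
  panels up to ~10⁵ SNPs on one core rather than biobank-scale data.
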
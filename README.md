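# condgwas

Conditional multi-locus association testing for quantitative-trait GWAS,
with closed-form power theory and Monte-Carlo validation.

## The problem

Genome-wide association studies usually test each SNP one at a time (the
single-locus test, **SLT**). When a trait already has SNPs with confirmed,
replicated effects, leaving those effects out of the model pushes their
genetic variance into the residual, which inflates the standard error of
every new candidate's estimate and costs power. The **multi-locus test
(MLT)** instead tests each candidate SNP *conditional* on the confirmed
set: the confirmed genotypes enter the regression as fixed covariates, the
residual shrinks back to σ², and weak new effects become easier to detect.

`condgwas` is for statistical geneticists who want to (a) quantify that
power gain analytically before collecting or reanalysing data, (b) verify
the formulae by simulation, and (c) run the conditional scan on genotype
data in VCF or PLINK-style additive text.

## The model

For subject *i* with phenotype *y<sub>i</sub>*, covariates
**Z**<sub>i</sub>, confirmed genotypes **G**<sub>i</sub> (minor-allele
counts 0/1/2) and candidate genotype *G<sub>i,s</sub>*:

> y<sub>i</sub> = μ + **Z**<sub>i</sub>**β**<sub>Z</sub> +
> **G**<sub>i</sub>**β**<sub>G</sub> + G<sub>i,s</sub>β<sub>s</sub> +
> e<sub>i</sub>,  e<sub>i</sub> ~ N(0, σ²)

The MLT t-tests H₀: β<sub>s</sub> = 0 in this full model (M = 1 + p + S
columns, df = N − M). Under Hardy–Weinberg and linkage equilibrium the
statistic is noncentral-t with noncentrality

> λ = β<sub>s</sub> / √(σ² / (N · 2p<sub>s</sub>q<sub>s</sub>))

and one-sided power P(T<sub>λ, N−M</sub> > t<sub>α</sub>). The SLT omits
**G**<sub>i</sub>, so its residual variance is inflated to

> σ\*² = σ² + Σ<sub>j</sub> β<sub>j</sub>² · 2p<sub>j</sub>q<sub>j</sub>,

its estimated standard errors grow by √(σ\*²/σ²), and its power becomes
P(T<sub>λ, N−p−2</sub> > t<sub>α</sub>·√(σ\*²/σ²)) — strictly lower
whenever the omitted effects are nonzero. Effect sizes are expressed in
residual-SD units (σ = 1 by default); the default significance convention
is α = 0.025 one-sided (the one-sided counterpart of two-sided 0.05).

## Worked example

2000 subjects, candidate SNP of effect 0.1 SD at maf 0.2, two confirmed
SNPs at mafs 0.3 and 0.4 swept over a shared effect size
(`python examples/01_power_comparison.py`):

```
 effect  power_mlt  power_slt  improvement
    0.1      0.715      0.712        0.003
    0.2      0.715      0.703        0.012
    0.3      0.715      0.688        0.027
    0.4      0.715      0.667        0.048
    0.5      0.715      0.640        0.075
    0.6      0.715      0.608        0.108
    0.7      0.715      0.570        0.145
    0.8      0.715      0.527        0.188
    0.9      0.715      0.481        0.235
    1.0      0.715      0.431        0.284
```

The MLT column is flat: once the confirmed SNPs are in the model their
effect sizes no longer matter for the candidate's test. The SLT column
decays as the omitted genetic variance grows, and the improvement reaches
0.284 when both confirmed effects are 1.0 SD. The same comparison on data
(`python examples/03_conditional_scan.py`) shows the mechanism per SNP: the
candidate's conditional fit has a smaller standard error (0.038 vs 0.042)
and a sharper p-value (0.040 vs 0.103) than its single-locus fit on the
same 2000 samples.

The other examples validate the formulae by simulation
(`02_simulation_validation.py`) and demonstrate LD pruning and Box-Cox
phenotype normalisation (`04_data_prep.py`).

## Command line

```sh
condgwas power --n 2000 --candidate 0.2,0.1 \
    --conditional 0.3,0.1 --conditional 0.4,0.1 --grid 0.1:1.0:0.1
condgwas simulate --n 2000 --reps 2000 --seed 7
condgwas scan --geno study.vcf --pheno pheno.tsv --conditional rs1,rs2
condgwas prune --geno study.vcf --effects effects.tsv --r2 0.8
condgwas boxcox --pheno pheno.tsv
```

Scans read VCF (GT field) or PLINK-style `.raw` additive text plus a
sidecar map; phenotypes/covariates are TSV with a sample-id first column.
Genotypes are always recoded to minor-allele counts from the observed
frequencies. Scans use complete cases per test (no imputation) and report
the per-SNP sample size.

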
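"""Quantitative-trait simulation under Hardy-Weinberg and linkage
equilibrium, and Monte-Carlo validation of the analytic power formulae.

Genotypes are unlinked biallelic SNPs with minor-allele counts drawn
Binomial(2, maf); phenotypes are a population mean plus additive SNP
effects plus Gaussian noise.  ``empirical_power`` repeatedly simulates a
cohort, fits the multi-locus (conditional) or single-locus model, applies
the candidate t-test, and reports the rejection proportion with its
Monte-Carlo standard error.  By convention the last SNP of a design is the
candidate and the preceding SNPs are the confirmed (conditional) loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .engine import GenotypeMatrix, fit_and_test
from .power import PowerScenario, SNPSpec, Sided

__all__ = [
    "SimulationDesign",
    "EmpiricalPowerEstimate",
    "simulate_genotypes",
    "simulate_phenotypes",
    "empirical_power",
    "design_from_scenario",
    "scenario_from_design",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one Monte-Carlo power study.

    The last entry of ``snps`` is the candidate SNP under test; all earlier
    entries are confirmed loci included in the multi-locus model.
    """

    n_subjects: int
    snps: tuple[SNPSpec, ...]
    mu: float = 0.0
    residual_sd: float = 1.0
    seed: int = 0
    n_reps: int = 2000
    covariate_effects: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(self.snps))
        object.__setattr__(
            self, "covariate_effects", tuple(self.covariate_effects)
        )
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.snps:
            raise ValueError("at least one SNP (the candidate) is required")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def candidate(self) -> SNPSpec:
        return self.snps[-1]

    @property
    def conditional(self) -> tuple[SNPSpec, ...]:
        return self.snps[:-1]


@dataclass(frozen=True)
class EmpiricalPowerEstimate:
    """Rejection proportion from a Monte-Carlo power study."""

    method: Literal["mlt", "slt"]
    rejections: int
    n_reps: int
    alpha: float
    sided: Sided
    seed: int
    redraws: int = 0  # replicates redrawn because a SNP came out monomorphic

    @property
    def power_hat(self) -> float:
        return self.rejections / self.n_reps

    @property
    def mc_se(self) -> float:
        p = self.power_hat
        return float(np.sqrt(p * (1.0 - p) / self.n_reps))


def _rep_rng(master_seed: int, rep: int) -> np.random.Generator:
    # counter-based: each replicate's stream is independent and individually
    # reproducible from (master seed, replicate index)
    return np.random.default_rng(np.random.SeedSequence((master_seed, rep)))


def simulate_genotypes(
    mafs: Sequence[float], n: int, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Unlinked HWE genotypes: each column iid Binomial(2, maf) minor-allele
    counts; no missing values."""
    mafs = np.asarray(list(mafs), float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError(f"mafs must be in (0, 0.5], got {mafs}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = rng.binomial(2, mafs, size=(n, mafs.size)).astype(float)
    return GenotypeMatrix(
        sample_ids=np.array([f"S{i + 1}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"snp{j + 1}" for j in range(mafs.size)], dtype=object),
        codes=codes,
        chrom=np.array(["1"] * mafs.size, dtype=object),
        pos=np.arange(1, mafs.size + 1) * 1000,
    )


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    effects: Sequence[float],
    mu: float = 0.0,
    residual_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """y = mu + G @ effects + e, with e ~ Normal(0, residual_sd^2)."""
    effects = np.asarray(list(effects), float)
    if effects.size != genotypes.n_snps:
        raise ValueError(
            f"{effects.size} effects for {genotypes.n_snps} genotype columns"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.normal(0.0, residual_sd, size=genotypes.n_samples)
    return mu + genotypes.codes @ effects + noise


def _simulate_replicate(
    design: SimulationDesign, rng: np.random.Generator, max_redraws: int = 100
) -> tuple[np.ndarray, np.ndarray, int]:
    """One cohort draw; monomorphic SNP columns trigger a full redraw."""
    mafs = [s.maf for s in design.snps]
    effects = [s.effect for s in design.snps]
    redraws = 0
    while True:
        geno = simulate_genotypes(mafs, design.n_subjects, rng)
        if all(np.unique(geno.codes[:, j]).size > 1 for j in range(geno.n_snps)):
            break
        redraws += 1
        if redraws > max_redraws:
            raise RuntimeError("persistent monomorphic draws; check maf and n")
    y = simulate_phenotypes(geno, effects, design.mu, design.residual_sd, rng)
    return geno.codes, y, redraws


def empirical_power(
    design: SimulationDesign,
    method: Literal["mlt", "slt"] = "mlt",
    alpha: float = 0.025,
    sided: Sided = "one",
) -> EmpiricalPowerEstimate:
    """Monte-Carlo rejection rate of the candidate-SNP t-test.

    Each replicate draws fresh genotypes and phenotypes, fits the
    multi-locus model (all confirmed SNPs as covariates) or the
    single-locus model (candidate only), and rejects when the candidate
    t-statistic exceeds the alpha-level central-t threshold.
    """
    if method not in ("mlt", "slt"):
        raise ValueError(f"method must be 'mlt' or 'slt', got {method!r}")
    rejections = 0
    redraws_total = 0
    for rep in range(design.n_reps):
        rng = _rep_rng(design.seed, rep)
        codes, y, redraws = _simulate_replicate(design, rng)
        redraws_total += redraws
        if method == "mlt":
            X = np.column_stack([np.ones(design.n_subjects), codes])
        else:
            X = np.column_stack([np.ones(design.n_subjects), codes[:, -1]])
        res = fit_and_test(y, X, sided, method=method)
        if res.p_value < alpha:
            rejections += 1
    return EmpiricalPowerEstimate(
        method=method,
        rejections=rejections,
        n_reps=design.n_reps,
        alpha=alpha,
        sided=sided,
        seed=design.seed,
        redraws=redraws_total,
    )


def design_from_scenario(
    scenario: PowerScenario, seed: int = 0, n_reps: int = 2000, mu: float = 0.0
) -> SimulationDesign:
    """Monte-Carlo design matching an analytic power scenario."""
    return SimulationDesign(
        n_subjects=scenario.n_subjects,
        snps=scenario.conditional + (scenario.candidate,),
        mu=mu,
        residual_sd=scenario.residual_sd,
        seed=seed,
        n_reps=n_reps,
    )


def scenario_from_design(
    design: SimulationDesign, alpha: float = 0.025, sided: Sided = "one"
) -> PowerScenario:
    """Analytic power scenario matching a Monte-Carlo design."""
    return PowerScenario(
        n_subjects=design.n_subjects,
        candidate=design.candidate,
        conditional=design.conditional,
        residual_sd=design.residual_sd,
        alpha=alpha,
        sided=sided,
    )
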
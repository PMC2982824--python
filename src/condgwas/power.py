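"""Closed-form power for the conditional multi-locus test (MLT) and the
single-locus test (SLT).

The MLT fits a multiple linear regression of a quantitative phenotype on an
intercept, ``p`` covariates, ``S - 1`` previously confirmed SNPs and one
candidate SNP (``M = 1 + p + S`` columns), and t-tests the candidate
coefficient ``beta_s``.  The SLT omits the confirmed SNPs, so their genetic
variance inflates the residual:

    sigma*^2 = sigma^2 + sum_j beta_j^2 * 2 p_j (1 - p_j)

Under Hardy-Weinberg and linkage equilibrium the candidate coefficient's
sampling variance is ``sigma^2 / (N * 2 p q)``, the test statistic is
noncentral-t with noncentrality ``lambda = beta_s / sqrt(sigma^2 c)``
(``c = 1/(N * 2 p q)``), and the SLT rejection threshold is effectively
scaled up by ``sqrt(sigma*^2 / sigma^2)`` because the SLT's estimated
residual variance converges to the inflated value.  Power for both tests
follows from the noncentral-t survival function.

Effect sizes throughout are in units of the residual standard deviation of
the full (MLT) model; genotype codes count copies of the minor allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SNPSpec",
    "PowerScenario",
    "PowerResult",
    "genotype_variance",
    "coefficient_variance",
    "mlt_noncentrality",
    "mlt_power",
    "slt_inflated_variance",
    "slt_power",
    "power_result",
    "power_table",
    "power_grid",
    "write_power_table",
    "write_power_grid",
]

Sided = Literal["one", "two"]


class DegenerateDesignError(np.linalg.LinAlgError):
    """Raised when a design matrix is (numerically) rank deficient."""


@dataclass(frozen=True)
class SNPSpec:
    """A biallelic SNP: minor-allele frequency and additive effect size.

    ``effect`` is the phenotype change per copy of the minor allele, in
    units of the residual SD of the full model.
    """

    label: str
    maf: float
    effect: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(
                f"SNP {self.label!r}: maf must be in (0, 0.5], got {self.maf}"
            )
        if not np.isfinite(self.effect):
            raise ValueError(f"SNP {self.label!r}: effect must be finite")

    @property
    def genotype_variance(self) -> float:
        return genotype_variance(self.maf)

    @property
    def explained_variance(self) -> float:
        """Additive genetic variance contributed by this SNP, beta^2 * 2pq."""
        return self.effect**2 * genotype_variance(self.maf)


@dataclass(frozen=True)
class PowerScenario:
    """Full parameterization of one MLT/SLT power comparison.

    ``conditional`` holds the S-1 confirmed SNPs whose effects the MLT
    includes and the SLT omits; ``candidate`` is the SNP under test with
    effect ``beta_s``.  ``n_covariates`` counts non-genetic covariates (p);
    only their number matters for the degrees of freedom.
    """

    n_subjects: int
    candidate: SNPSpec
    conditional: tuple[SNPSpec, ...] = ()
    n_covariates: int = 0
    residual_sd: float = 1.0
    alpha: float = 0.025
    sided: Sided = "one"

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditional", tuple(self.conditional))
        if self.n_subjects <= self.n_model_columns:
            raise ValueError(
                f"n_subjects={self.n_subjects} must exceed the model column "
                f"count M={self.n_model_columns}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.sided not in ("one", "two"):
            raise ValueError(f"sided must be 'one' or 'two', got {self.sided!r}")

    @property
    def n_snps(self) -> int:
        """S: conditional SNPs plus the candidate."""
        return len(self.conditional) + 1

    @property
    def n_model_columns(self) -> int:
        """M = 1 + p + S columns of the full (MLT) design."""
        return 1 + self.n_covariates + self.n_snps

    @property
    def df_mlt(self) -> int:
        return self.n_subjects - self.n_model_columns

    @property
    def df_slt(self) -> int:
        return self.n_subjects - self.n_covariates - 2


@dataclass(frozen=True)
class PowerResult:
    """Analytic MLT/SLT power with diagnostics for one scenario."""

    power_mlt: float
    power_slt: float
    noncentrality: float
    inflated_residual_variance: float
    df_mlt: int
    df_slt: int
    threshold_scale: float

    @property
    def improvement(self) -> float:
        return self.power_mlt - self.power_slt


def genotype_variance(maf: float) -> float:
    """Variance of the 0/1/2 minor-allele-count code under Hardy-Weinberg.

    For genotype counts Binomial(2, maf) this is ``2 * maf * (1 - maf)``.
    """
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"maf must be in [0, 0.5], got {maf}")
    return 2.0 * maf * (1.0 - maf)


def _expected_c(scenario: PowerScenario) -> float:
    """Large-sample (X'X)^-1 candidate diagonal under HWE + linkage equilibrium."""
    gv = genotype_variance(scenario.candidate.maf)
    if gv <= 0.0:
        raise ValueError("candidate genotype variance is zero (monomorphic SNP)")
    return 1.0 / (scenario.n_subjects * gv)


def _realized_c(design: np.ndarray, column: int) -> float:
    design = np.asarray(design, dtype=float)
    xtx = design.T @ design
    rcond = 1.0 / np.linalg.cond(xtx) if xtx.size else 0.0
    if not np.isfinite(rcond) or rcond < 1e-12:
        corr = np.corrcoef(design[:, 1:], rowvar=False)
        pairs = [
            (i + 1, j + 1)
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 0.999
        ]
        raise DegenerateDesignError(
            f"design matrix is singular; collinear column pairs: {pairs or 'unknown'}"
        )
    return float(np.linalg.inv(xtx)[column, column])


def coefficient_variance(
    scenario: PowerScenario,
    method: Literal["mlt", "slt"] = "mlt",
    mode: Literal["expected", "realized"] = "expected",
    design: np.ndarray | None = None,
) -> float:
    """Sampling variance of the candidate-coefficient estimate.

    ``expected`` mode returns the closed-form large-sample value under HWE
    and linkage equilibrium, ``sigma_eff^2 / (N * 2 p q)``, where the
    effective residual variance is ``sigma^2`` for the MLT and the inflated
    ``sigma*^2`` for the SLT.  ``realized`` mode evaluates the corresponding
    diagonal element of ``(X'X)^-1`` on a supplied design matrix (candidate
    genotype in the last column).
    """
    if method not in ("mlt", "slt"):
        raise ValueError(f"method must be 'mlt' or 'slt', got {method!r}")
    sigma2 = scenario.residual_sd**2
    sigma2_eff = (
        sigma2
        if method == "mlt"
        else slt_inflated_variance(sigma2, scenario.conditional)
    )
    if mode == "expected":
        return sigma2_eff * _expected_c(scenario)
    if mode == "realized":
        if design is None:
            raise ValueError("realized mode requires a design matrix")
        return sigma2_eff * _realized_c(np.asarray(design, float), -1)
    raise ValueError(f"mode must be 'expected' or 'realized', got {mode!r}")


def mlt_noncentrality(scenario: PowerScenario) -> float:
    """Noncentrality lambda = beta_s / sqrt(var(beta_s_hat)) of the MLT t-test."""
    return scenario.candidate.effect / np.sqrt(
        coefficient_variance(scenario, "mlt", "expected")
    )


def slt_inflated_variance(
    residual_variance: float, conditional: Iterable[SNPSpec]
) -> float:
    """SLT residual variance: sigma^2 plus the omitted conditional SNPs'
    additive genetic variance (SNPs mutually in linkage equilibrium)."""
    if residual_variance <= 0:
        raise ValueError("residual_variance must be positive")
    return residual_variance + sum(s.explained_variance for s in conditional)


def _noncentral_t_power(
    df: int, lam: float, alpha: float, sided: Sided, scale: float = 1.0
) -> float:
    """P(reject) for a noncentral-t statistic against a (scaled) central-t
    threshold.  One-sided rejects in the upper tail; two-sided in both."""
    if df <= 0:
        raise ValueError(f"insufficient degrees of freedom (df={df})")
    if sided == "one":
        t_alpha = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(t_alpha * scale, df, lam))
    t_alpha = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = stats.nct.sf(t_alpha * scale, df, lam)
    lower = stats.nct.cdf(-t_alpha * scale, df, lam)
    return float(upper + lower)


def mlt_power(scenario: PowerScenario) -> float:
    """Power of the conditional (multi-locus) t-test of the candidate SNP.

    The statistic is noncentral-t with N - M degrees of freedom; because the
    confirmed SNPs are in the model, the residual variance is sigma^2 and
    power does not depend on the conditional effect sizes.
    """
    if scenario.df_mlt <= 0:
        raise ValueError(
            f"insufficient df: N={scenario.n_subjects} <= M={scenario.n_model_columns}"
        )
    lam = mlt_noncentrality(scenario)
    return _noncentral_t_power(scenario.df_mlt, lam, scenario.alpha, scenario.sided)


def slt_power(scenario: PowerScenario) -> float:
    """Power of the single-locus t-test when the conditional effects are omitted.

    The omitted effects inflate the estimated residual variance to sigma*^2,
    so the realized rejection threshold is the central-t quantile scaled by
    sqrt(sigma*^2 / sigma^2), applied to a noncentral-t statistic with
    N - p - 2 degrees of freedom and the same lambda as the MLT (expressed
    on the sigma^2 scale).
    """
    if scenario.df_slt <= 0:
        raise ValueError(
            f"insufficient df: N={scenario.n_subjects} <= p+2="
            f"{scenario.n_covariates + 2}"
        )
    sigma2 = scenario.residual_sd**2
    sigma_star2 = slt_inflated_variance(sigma2, scenario.conditional)
    scale = np.sqrt(sigma_star2 / sigma2)
    lam = scenario.candidate.effect / np.sqrt(sigma2 * _expected_c(scenario))
    return _noncentral_t_power(scenario.df_slt, lam, scenario.alpha, scenario.sided, scale)


def power_result(scenario: PowerScenario) -> PowerResult:
    """Both powers plus diagnostics for one scenario."""
    sigma2 = scenario.residual_sd**2
    sigma_star2 = slt_inflated_variance(sigma2, scenario.conditional)
    return PowerResult(
        power_mlt=mlt_power(scenario),
        power_slt=slt_power(scenario),
        noncentrality=mlt_noncentrality(scenario),
        inflated_residual_variance=sigma_star2,
        df_mlt=scenario.df_mlt,
        df_slt=scenario.df_slt,
        threshold_scale=float(np.sqrt(sigma_star2 / sigma2)),
    )


def power_table(
    base_scenario: PowerScenario, conditional_effect_grid: Sequence[float]
):
    """Sweep a common effect size over ALL conditional SNPs of the base
    scenario and tabulate MLT power, SLT power and the improvement.

    Returns a pandas DataFrame with columns
    ``effect, power_mlt, power_slt, improvement``; the MLT column is
    constant across rows because the conditional effects are in the model.
    """
    import pandas as pd

    grid = list(conditional_effect_grid)
    if not grid:
        raise ValueError("conditional_effect_grid must be nonempty")
    rows = []
    for effect in grid:
        scen = PowerScenario(
            n_subjects=base_scenario.n_subjects,
            candidate=base_scenario.candidate,
            conditional=tuple(
                SNPSpec(s.label, s.maf, effect) for s in base_scenario.conditional
            ),
            n_covariates=base_scenario.n_covariates,
            residual_sd=base_scenario.residual_sd,
            alpha=base_scenario.alpha,
            sided=base_scenario.sided,
        )
        res = power_result(scen)
        rows.append(
            {
                "effect": effect,
                "power_mlt": res.power_mlt,
                "power_slt": res.power_slt,
                "improvement": res.improvement,
            }
        )
    return pd.DataFrame(rows)


def power_grid(
    conditional: Sequence[SNPSpec],
    candidate_effect_grid: Sequence[float],
    candidate_maf_grid: Sequence[float],
    n: int,
    alpha: float = 0.025,
    sided: Sided = "one",
    n_covariates: int = 0,
    residual_sd: float = 1.0,
):
    """Improvement (MLT power minus SLT power) over a candidate effect x maf
    grid, for a fixed conditional-SNP set.  Mirrors the heatmap summaries
    used to assess how much conditioning on confirmed loci helps.

    Returns a pandas DataFrame indexed by candidate effect (rows) with
    candidate maf as columns.
    """
    import pandas as pd

    effects = list(candidate_effect_grid)
    mafs = list(candidate_maf_grid)
    if not effects or not mafs:
        raise ValueError("grids must be nonempty")
    values = np.empty((len(effects), len(mafs)))
    for i, eff in enumerate(effects):
        for j, maf in enumerate(mafs):
            scen = PowerScenario(
                n_subjects=n,
                candidate=SNPSpec("candidate", maf, eff),
                conditional=tuple(conditional),
                n_covariates=n_covariates,
                residual_sd=residual_sd,
                alpha=alpha,
                sided=sided,
            )
            values[i, j] = mlt_power(scen) - slt_power(scen)
    return pd.DataFrame(values, index=pd.Index(effects, name="effect"),
                        columns=pd.Index(mafs, name="maf"))


def write_power_table(table, path, header_lines: Sequence[str] = ()) -> None:
    """Write a power table as TSV with optional '#' provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_power_grid(grid, path, header_lines: Sequence[str] = ()) -> None:
    """Write an improvement grid as TSV with row/column coordinate headers."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        grid.to_csv(fh, sep="\t", float_format="%.6g")
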
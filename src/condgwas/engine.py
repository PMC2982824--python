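"""Conditional association testing on genotype data.

The scan fits, for each candidate SNP, an ordinary least-squares regression
of the phenotype on an intercept, numeric covariates, the confirmed
("conditional") SNPs and the candidate, and t-tests the candidate
coefficient (the multi-locus test, MLT).  The single-locus test (SLT) is
the same fit with the conditional set empty.  Samples with any missing
value among the columns a given test uses are dropped (complete case, no
imputation), so the MLT and SLT sample sizes can differ per SNP.

Also provides the data-preparation steps a conditional scan needs:
minor-allele-frequency filtering, r^2-based LD pruning that keeps the
largest-effect SNP per high-LD region, and Box-Cox selection of a
normalising phenotype transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .power import DegenerateDesignError, Sided

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "AssocResult",
    "build_design",
    "fit_and_test",
    "conditional_scan",
    "r_square",
    "ld_prune",
    "boxcox_select",
    "results_to_frame",
    "write_results",
]

#: reciprocal condition number below which a design is declared degenerate
RCOND_CUTOFF = 1e-10


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele-count codes (0/1/2, NaN = missing)."""

    sample_ids: np.ndarray  # (n,) str
    snp_ids: np.ndarray  # (m,) str
    codes: np.ndarray  # (n, m) float, values in {0, 1, 2, nan}
    chrom: np.ndarray | None = None  # (m,) str
    pos: np.ndarray | None = None  # (m,) int, 1-based
    minor_allele: np.ndarray | None = None  # (m,) str

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        return self.codes[:, self.index_of(snp_id)]

    def index_of(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(
                f"SNP {snp_id!r} not found; available ids include "
                f"{list(self.snp_ids[:10])}"
            )
        return int(hits[0])

    def maf(self, snp_id: str | None = None) -> np.ndarray | float:
        """Observed minor-allele frequency (codes are minor-allele counts)."""
        if snp_id is not None:
            col = self.column(snp_id)
            return float(np.nanmean(col) / 2.0)
        return np.nanmean(self.codes, axis=0) / 2.0


@dataclass
class PhenotypeTable:
    """One phenotype plus numeric covariates, one row per sample."""

    frame: pd.DataFrame  # index = sample id; first column = phenotype
    phenotype: str | None = None

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.phenotype is None:
            self.phenotype = self.frame.columns[0]
        non_numeric = [
            c for c in self.frame.columns
            if not pd.api.types.is_numeric_dtype(self.frame[c])
        ]
        if non_numeric:
            raise ValueError(
                f"columns {non_numeric} are not numeric; encode covariates "
                "numerically before building the table"
            )

    @property
    def sample_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy(dtype=object)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.phenotype]


@dataclass(frozen=True)
class AssocResult:
    """One candidate SNP's conditional (or single-locus) test result."""

    snp_id: str
    beta_hat: float
    se: float
    t_stat: float
    df: int
    p_value: float
    n_used: int
    method: Literal["mlt", "slt"]
    conditional_ids: tuple[str, ...] = ()
    chrom: str | None = None
    pos: int | None = None


def build_design(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    conditional_ids: Sequence[str],
    candidate_id: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (response, design, sample ids used) for one candidate test.

    Design columns are ordered (intercept, covariates, conditional
    genotypes, candidate genotype), so the candidate coefficient is the
    last (Mth) element.  Samples are matched by id and any sample missing
    a value in any used column is dropped.
    """
    conditional_ids = list(conditional_ids)
    if candidate_id in conditional_ids:
        raise ValueError(f"candidate {candidate_id!r} is in the conditional set")
    shared, p_idx, g_idx = np.intersect1d(
        pheno.sample_ids.astype(str),
        geno.sample_ids.astype(str),
        return_indices=True,
    )
    if shared.size == 0:
        raise ValueError("no shared sample ids between phenotype and genotype data")
    y = pheno.frame[pheno.phenotype].to_numpy(float)[p_idx]
    covs = pheno.frame[pheno.covariates].to_numpy(float)[p_idx]
    g_cols = np.column_stack(
        [geno.column(s)[g_idx] for s in conditional_ids + [candidate_id]]
    )
    design = np.column_stack([np.ones(shared.size), covs, g_cols])
    keep = ~(np.isnan(y) | np.isnan(design).any(axis=1))
    return y[keep], design[keep], shared[keep]


def _check_rank(design: np.ndarray) -> None:
    xtx = design.T @ design
    # singular values of X'X; rcond mirrors numpy's matrix_rank convention
    svals = np.linalg.svd(xtx, compute_uv=False)
    if svals[0] <= 0 or svals[-1] / svals[0] < RCOND_CUTOFF:
        k = design.shape[1]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(design.T)
        pairs = [
            (i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if np.isfinite(corr[i, j]) and abs(corr[i, j]) > 0.999
        ]
        raise DegenerateDesignError(
            f"rank-deficient design; near-collinear column pairs: {pairs or 'unknown'}"
        )


def fit_and_test(
    response: np.ndarray,
    design: np.ndarray,
    sided: Sided = "two",
    *,
    snp_id: str = "",
    method: Literal["mlt", "slt"] = "mlt",
    conditional_ids: Sequence[str] = (),
    chrom: str | None = None,
    pos: int | None = None,
) -> AssocResult:
    """OLS fit of response on design; t-test of the last coefficient.

    The standard error comes from the last diagonal element of
    ``sigma_hat^2 (X'X)^-1`` with the usual unbiased residual-variance
    estimate; one-sided p-values test the upper tail (positive effect).
    """
    y = np.asarray(response, float)
    X = np.asarray(design, float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError(f"response length {y.shape} does not match design rows {n}")
    if n <= k:
        raise ValueError(f"insufficient data: n_used={n} <= {k} design columns")
    _check_rank(X)
    xtx = X.T @ X
    xtx_inv = linalg.inv(xtx, check_finite=False)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2_hat = float(resid @ resid) / df
    se = float(np.sqrt(sigma2_hat * xtx_inv[-1, -1]))
    b = float(beta[-1])
    if se == 0.0:
        t_stat = np.inf if b > 0 else (-np.inf if b < 0 else 0.0)
    else:
        t_stat = b / se
    if sided == "one":
        p = float(stats.t.sf(t_stat, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return AssocResult(
        snp_id=snp_id,
        beta_hat=b,
        se=se,
        t_stat=float(t_stat),
        df=df,
        p_value=min(p, 1.0),
        n_used=n,
        method=method,
        conditional_ids=tuple(conditional_ids),
        chrom=chrom,
        pos=pos,
    )


def conditional_scan(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    conditional_ids: Sequence[str] = (),
    method: Literal["mlt", "slt"] = "mlt",
    sided: Sided = "two",
    maf_min: float = 0.01,
) -> tuple[list[AssocResult], dict[str, str]]:
    """Test every SNP passing the MAF filter, conditional on the confirmed set.

    With ``method='slt'`` the conditional set is ignored in each fit.  A
    conditional SNP itself is tested conditional on the *other* confirmed
    SNPs (leave one out).  Returns (results sorted by genomic position,
    per-SNP failure messages); per-SNP failures are recorded, not fatal.
    """
    conditional_ids = list(conditional_ids)
    for cid in conditional_ids:
        geno.index_of(cid)  # raises KeyError listing available ids
    mafs = geno.maf()
    results: list[AssocResult] = []
    failures: dict[str, str] = {}
    for j, snp in enumerate(geno.snp_ids):
        snp = str(snp)
        if mafs[j] < maf_min:
            continue
        cond = [c for c in conditional_ids if c != snp] if method == "mlt" else []
        try:
            y, X, used = build_design(pheno, geno, cond, snp)
            res = fit_and_test(
                y, X, sided,
                snp_id=snp, method=method, conditional_ids=cond,
                chrom=str(geno.chrom[j]) if geno.chrom is not None else None,
                pos=int(geno.pos[j]) if geno.pos is not None else None,
            )
            results.append(res)
        except (DegenerateDesignError, ValueError) as exc:
            failures[snp] = str(exc)
    if geno.pos is not None:
        results.sort(key=lambda r: ((r.chrom or ""), r.pos if r.pos is not None else 0))
    return results, failures


def r_square(geno: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two SNPs' codes over complete cases."""
    a = geno.column(snp_a)
    b = geno.column(snp_b)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError(
            f"r^2 undefined: {snp_a!r} or {snp_b!r} is monomorphic on the "
            f"{keep.sum()} shared complete cases"
        )
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    candidates: Sequence[tuple],
    geno: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window: int = 1_000_000,
) -> list:
    """Keep one SNP per high-LD region, preferring the largest |effect|.

    ``candidates`` is a sequence of (SNPSpec, position) pairs whose labels
    index ``geno``.  Greedy by descending |effect| (ties by position then
    label): a SNP is kept iff its r^2 with every already-kept SNP within
    ``window`` bp is below ``r2_threshold``.  Output preserves genomic
    order.
    """
    order = sorted(
        candidates, key=lambda sp: (-abs(sp[0].effect), sp[1], sp[0].label)
    )
    kept: list[tuple] = []
    for spec, position in order:
        clash = False
        for kspec, kpos in kept:
            if abs(position - kpos) <= window:
                if r_square(geno, spec.label, kspec.label) >= r2_threshold:
                    clash = True
                    break
        if not clash:
            kept.append((spec, position))
    kept.sort(key=lambda sp: sp[1])
    return kept


def boxcox_select(
    y: np.ndarray, lambda_grid: Sequence[float]
) -> tuple[float, np.ndarray, np.ndarray]:
    """Box-Cox transform selection by profile log-likelihood over a grid.

    Returns (selected lambda, transformed values, profile log-likelihood per
    grid value).  lambda = 0 is the log transform; the full profile is
    returned so "approximately log" can be assessed rather than asserted.
    """
    y = np.asarray(y, float)
    grid = np.asarray(list(lambda_grid), float)
    if grid.size == 0:
        raise ValueError("lambda_grid must be nonempty")
    if np.any(y <= 0):
        raise ValueError(
            "Box-Cox requires strictly positive values; shift the phenotype "
            "before transforming"
        )
    loglik = np.array([stats.boxcox_llf(lam, y) for lam in grid])
    best = grid[int(np.argmax(loglik))]
    transformed = stats.boxcox(y, lmbda=best)
    return float(best), transformed, loglik


def results_to_frame(results: Iterable[AssocResult]) -> pd.DataFrame:
    rows = [
        {
            "snp": r.snp_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "n_used": r.n_used,
            "beta": r.beta_hat,
            "se": r.se,
            "t": r.t_stat,
            "df": r.df,
            "p": r.p_value,
            "method": r.method,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["snp", "chrom", "pos", "n_used", "beta", "se", "t", "df", "p", "method"],
    )


def write_results(results: Iterable[AssocResult], path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        results_to_frame(results).to_csv(fh, sep="\t", index=False, float_format="%.6g")
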
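"""Readers and writers for genotype, phenotype and results files, plus a
synthetic-fixture generator for end-to-end tests.

Genotype formats: VCF v4.x (GT field only; uncompressed text) and
PLINK-style additive text (.raw dialect: ``FID IID PAT MAT SEX PHENOTYPE``
then one 0/1/2/NA column per SNP) with a sidecar map (snp, chrom, 1-based
pos).  In both cases the in-memory coding is the count of the MINOR allele,
recomputed per SNP from the observed allele frequencies rather than taken
from REF/ALT orientation, because the association model is written in
minor-allele copies; a tie at frequency 0.5 resolves to the ALT (or
counted) allele.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import GenotypeMatrix, PhenotypeTable
from .simulate import SimulationDesign, simulate_genotypes, simulate_phenotypes

__all__ = [
    "FixtureBundle",
    "read_genotypes",
    "write_vcf",
    "write_raw",
    "read_pheno",
    "write_pheno",
    "make_fixtures",
]


class ParseError(ValueError):
    """A genotype or phenotype file failed to parse."""


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of one generated synthetic dataset (genotypes in both dialects,
    phenotypes, and a truth file recording the planted effects and seed)."""

    vcf: Path
    raw: Path
    map: Path
    pheno: Path
    truth: Path


def _orient_to_minor(dosage: np.ndarray, ref: str, alt: str) -> tuple[np.ndarray, str]:
    """Re-code an ALT-allele dosage column to minor-allele counts."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing column
        alt_freq = np.nanmean(dosage) / 2.0
    if np.isnan(alt_freq) or alt_freq <= 0.5:  # tie at 0.5 -> ALT is "minor"
        return dosage, alt
    return 2.0 - dosage, ref


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare Exception subclasses
        raise ParseError(f"{path}: not a readable VCF: {exc}") from exc
    samples = np.array(vcf.samples, dtype=object)
    snp_ids, chroms, positions, minors, columns = [], [], [], [], []
    n_skipped = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([0.0, 1.0, np.nan, 2.0])
    for record_no, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        dosage = gt_map[variant.gt_types]
        codes, minor = _orient_to_minor(dosage, variant.REF, variant.ALT[0])
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(str(variant.CHROM))
        positions.append(int(variant.POS))
        minors.append(minor)
        columns.append(codes)
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-biallelic site(s)")
    codes = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(
        sample_ids=samples,
        snp_ids=np.array(snp_ids, dtype=object),
        codes=codes,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=int),
        minor_allele=np.array(minors, dtype=object),
    )


_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _read_raw(path, map_path=None) -> GenotypeMatrix:
    try:
        frame = pd.read_csv(path, sep=r"\s+", dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse .raw file: {exc}") from exc
    missing_meta = [c for c in _RAW_META if c not in frame.columns]
    if missing_meta:
        raise ParseError(f"{path}: missing .raw columns {missing_meta}")
    snp_columns = [c for c in frame.columns if c not in _RAW_META]
    snp_ids, minors, columns = [], [], []
    for col in snp_columns:
        snp_id, _, counted = col.rpartition("_")
        if not snp_id:
            snp_id, counted = col, ""
        raw_vals = frame[col].replace("NA", np.nan).astype(float)
        bad = raw_vals.dropna()[~raw_vals.dropna().isin([0.0, 1.0, 2.0])]
        if len(bad):
            row = int(bad.index[0])
            raise ParseError(
                f"{path}: line {row + 2}, column {col!r}: genotype "
                f"{bad.iloc[0]!r} is not 0/1/2/NA"
            )
        dosage = raw_vals.to_numpy(float)
        codes, minor = _orient_to_minor(dosage, "", counted)
        snp_ids.append(snp_id)
        minors.append(minor if minor else None)
        columns.append(codes)
    chrom = pos = None
    if map_path is not None:
        mp = pd.read_csv(map_path, sep="\t", dtype={"snp": str, "chrom": str})
        mp = mp.set_index("snp").reindex(snp_ids)
        chrom = mp["chrom"].to_numpy(dtype=object)
        pos = mp["pos"].to_numpy(dtype=int)
    return GenotypeMatrix(
        sample_ids=frame["IID"].to_numpy(dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        codes=np.column_stack(columns) if columns else np.empty((len(frame), 0)),
        chrom=chrom,
        pos=pos,
        minor_allele=np.array(minors, dtype=object),
    )


def read_genotypes(path, format: str = "vcf", map_path=None) -> GenotypeMatrix:
    """Read genotypes as minor-allele counts.

    ``format='vcf'`` reads VCF v4.x via cyvcf2 (GT only; non-biallelic
    sites skipped with a warning); ``format='raw'`` reads PLINK-style
    additive text, optionally joining a sidecar map for coordinates.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "raw":
        return _read_raw(path, map_path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF.  The ALT allele is the stored minor
    allele, so ALT dosage equals the minor-allele code."""
    gt_by_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=condgwas\n")
        chroms = (
            geno.chrom if geno.chrom is not None else np.array(["1"], dtype=object)
        )
        for chrom in dict.fromkeys(map(str, chroms)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.sample_ids))
            + "\n"
        )
        for j, snp in enumerate(geno.snp_ids):
            chrom = geno.chrom[j] if geno.chrom is not None else "1"
            pos = geno.pos[j] if geno.pos is not None else (j + 1) * 1000
            alt = (
                geno.minor_allele[j]
                if geno.minor_allele is not None and geno.minor_allele[j]
                else "G"
            )
            ref = "A" if alt != "A" else "C"
            gts = [
                gt_by_code.get(code, "./.") for code in geno.codes[:, j]
            ]
            fh.write(
                f"{chrom}\t{pos}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_raw(geno: GenotypeMatrix, path, map_path=None) -> None:
    """Write PLINK-style additive text (and optionally the sidecar map)."""
    with open(path, "w") as fh:
        headers = [
            f"{snp}_{geno.minor_allele[j]}"
            if geno.minor_allele is not None and geno.minor_allele[j]
            else str(snp)
            for j, snp in enumerate(geno.snp_ids)
        ]
        fh.write(" ".join(_RAW_META + headers) + "\n")
        for i, sid in enumerate(geno.sample_ids):
            row = [str(sid), str(sid), "0", "0", "0", "-9"]
            for code in geno.codes[i]:
                row.append("NA" if np.isnan(code) else str(int(code)))
            fh.write(" ".join(row) + "\n")
    if map_path is not None:
        mp = pd.DataFrame(
            {
                "snp": geno.snp_ids,
                "chrom": geno.chrom if geno.chrom is not None else "1",
                "pos": geno.pos
                if geno.pos is not None
                else (np.arange(geno.n_snps) + 1) * 1000,
            }
        )
        mp.to_csv(map_path, sep="\t", index=False)


def read_pheno(path, phenotype: str | None = None) -> PhenotypeTable:
    """Read a tab-separated phenotype/covariate table (header required,
    first column sample id, NA = missing)."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"])
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: need a sample-id column plus data columns")
    frame = frame.set_index(frame.columns[0])
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()
                             & frame[col].notna()]
            where = f"row {bad.index[0]!r}" if len(bad) else "unknown row"
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at {where}"
            )
    return PhenotypeTable(frame=frame, phenotype=phenotype)


def write_pheno(pheno: PhenotypeTable, path) -> None:
    pheno.frame.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def make_fixtures(design: SimulationDesign, out_dir) -> FixtureBundle:
    """Generate one synthetic dataset on disk, deterministic under the seed.

    Writes genotypes in both dialects, a phenotype table, and a truth file
    (JSON) recording the planted effects so expected scan behaviour can be
    re-derived.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0)))
    geno = simulate_genotypes(
        [s.maf for s in design.snps], design.n_subjects, rng
    )
    geno.snp_ids = np.array([s.label for s in design.snps], dtype=object)
    geno.minor_allele = np.array(["G"] * geno.n_snps, dtype=object)
    y = simulate_phenotypes(
        geno, [s.effect for s in design.snps], design.mu, design.residual_sd, rng
    )
    pheno = PhenotypeTable(
        frame=pd.DataFrame({"phenotype": np.round(y, 8)}, index=geno.sample_ids),
    )
    bundle = FixtureBundle(
        vcf=out / "genotypes.vcf",
        raw=out / "genotypes.raw",
        map=out / "genotypes.map.tsv",
        pheno=out / "phenotypes.tsv",
        truth=out / "truth.json",
    )
    write_vcf(geno, bundle.vcf)
    write_raw(geno, bundle.raw, bundle.map)
    write_pheno(pheno, bundle.pheno)
    truth = {
        "seed": design.seed,
        "n_subjects": design.n_subjects,
        "mu": design.mu,
        "residual_sd": design.residual_sd,
        "snps": [
            {"label": s.label, "maf": s.maf, "effect": s.effect}
            for s in design.snps
        ],
        "candidate": design.candidate.label,
    }
    bundle.truth.write_text(json.dumps(truth, indent=2) + "\n")
    return bundle
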
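"""A conditional genome scan on a small synthetic dataset.

Generates fixture files (VCF + phenotype table) with two strong confirmed
SNPs and one weak candidate, then scans every SNP conditional on the
confirmed pair and side by side without conditioning.
"""

import tempfile

from condgwas import (
    SimulationDesign,
    SNPSpec,
    conditional_scan,
    make_fixtures,
    read_genotypes,
    read_pheno,
    results_to_frame,
)

design = SimulationDesign(
    n_subjects=2000,
    snps=(
        SNPSpec("conf1", 0.3, 0.5),
        SNPSpec("conf2", 0.4, 0.4),
        SNPSpec("cand", 0.2, 0.1),
    ),
    seed=7,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = make_fixtures(design, tmp)
    geno = read_genotypes(bundle.vcf, "vcf")
    pheno = read_pheno(bundle.pheno)
    mlt, _ = conditional_scan(geno, pheno, ["conf1", "conf2"], method="mlt")
    slt, _ = conditional_scan(geno, pheno, [], method="slt")

print("Conditional on conf1 + conf2 (confirmed SNPs, leave-one-out):")
print(results_to_frame(mlt).round(4).to_string(index=False))
print("\nSingle-locus (no conditioning):")
print(results_to_frame(slt).round(4).to_string(index=False))
print(
    "\nThe candidate's conditional standard error is smaller because the "
    "confirmed\neffects no longer sit in the residual, so its p-value is "
    "usually sharper."
)
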
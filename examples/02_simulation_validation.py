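"""Monte-Carlo validation of the analytic power formulae.

Simulates cohorts of 2000 subjects with three unlinked Hardy-Weinberg SNPs
(confirmed effects 0.3 and 0.2 SD, candidate 0.1 SD), tests the candidate
with both methods in each replicate, and compares the rejection proportion
with the closed-form prediction.
"""

from condgwas import (
    SimulationDesign,
    SNPSpec,
    empirical_power,
    mlt_power,
    scenario_from_design,
    slt_power,
)

design = SimulationDesign(
    n_subjects=2000,
    snps=(
        SNPSpec("conf1", 0.3, 0.3),
        SNPSpec("conf2", 0.4, 0.2),
        SNPSpec("candidate", 0.2, 0.1),
    ),
    seed=42,
    n_reps=2000,
)
scenario = scenario_from_design(design)

for method, analytic in (
    ("mlt", mlt_power(scenario)),
    ("slt", slt_power(scenario)),
):
    est = empirical_power(design, method, alpha=0.025, sided="one")
    print(
        f"{method}: empirical {est.power_hat:.3f} (MC SE {est.mc_se:.3f}) "
        f"vs analytic {analytic:.3f}"
    )
print(
    "\nThe empirical proportions should sit within ~2 Monte-Carlo standard "
    "errors of\nthe analytic values; the MLT rate exceeds the SLT rate "
    "because the SLT leaves\nthe confirmed effects in its residual."
)
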
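import numpy as np
import pytest

from condgwas import PowerScenario, SNPSpec, SimulationDesign


@pytest.fixture
def benchmark_scenario() -> PowerScenario:
    """N=2000, candidate maf 0.2 / effect 0.1 SD, two confirmed SNPs with
    mafs 0.3 and 0.4 — the reference comparison scenario."""
    return PowerScenario(
        n_subjects=2000,
        candidate=SNPSpec("candidate", maf=0.2, effect=0.1),
        conditional=(
            SNPSpec("conf1", maf=0.3, effect=0.1),
            SNPSpec("conf2", maf=0.4, effect=0.1),
        ),
    )


@pytest.fixture
def validation_design() -> SimulationDesign:
    """Simulation design matching the analytic benchmark: confirmed effects
    0.3 and 0.2 SD, candidate 0.1 SD, mafs 0.3/0.4/0.2."""
    return SimulationDesign(
        n_subjects=2000,
        snps=(
            SNPSpec("conf1", 0.3, 0.3),
            SNPSpec("conf2", 0.4, 0.2),
            SNPSpec("candidate", 0.2, 0.1),
        ),
        seed=1234,
        n_reps=500,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
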
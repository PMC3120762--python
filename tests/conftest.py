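import numpy as np
import pytest

from phylodeme.simulate import SimulationConfig, generate_dataset, GrowthSpec
from phylodeme.scenarios import get_scenario


@pytest.fixture(scope="session")
def toy_alignment():
    """Six sequences, two demes, three distinct haplotypes."""
    aln = {
        "a1": "ACGTACGT",
        "a2": "ACGTACGT",
        "a3": "ACGAACGT",
        "b1": "ACGTACGT",
        "b2": "ACGAACGT",
        "b3": "TCGAACGT",
    }
    dm = {"a1": "X", "a2": "X", "a3": "X", "b1": "Y", "b2": "Y", "b3": "Y"}
    return aln, dm


@pytest.fixture(scope="session")
def coi_like_dataset():
    """One default COI-shaped synthetic dataset (138 records, 604 bp)."""
    return generate_dataset(SimulationConfig.coi_like(seed=42))


@pytest.fixture(scope="session")
def recovery_dataset():
    """A dataset at the model-recovery study conditions (no growth,
    3 x 20 sequences, 600 bp, theta 0.01, strong directional rates)."""
    cfg = SimulationConfig(sample_sizes=(20, 20, 20), theta=0.01,
                           migration_rates=100.0, growth=None,
                           locus_length=600, seed=7)
    return generate_dataset(cfg)
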
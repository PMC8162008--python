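import numpy as np
import pytest

from expherit.grm import compute_grm, maf_filter
from expherit.sim import SimulationSpec, simulate_dataset, simulate_genotypes


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale dataset: 30 lines, 2 chromosomes of 10 Mb, 120 genes."""
    return SimulationSpec(
        n_genotypes=30,
        n_markers=400,
        n_chromosomes=2,
        chromosome_length_bp=10_000_000,
        n_genes=120,
        hotspot_spec=(("Chr1", 4_000_001, 5_500_000, 8),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return simulate_dataset(small_spec)


@pytest.fixture(scope="session")
def panel_kinship():
    """GRM of a full-size (84-line) simulated panel, as the study uses."""
    geno = simulate_genotypes(SimulationSpec(seed=7))
    return compute_grm(maf_filter(geno))
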
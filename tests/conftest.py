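import pytest
from hypothesis import settings

from kojigenomics.core_io import CladeAssignment
from kojigenomics.synthetic_data import SimConfig, simulate_dataset

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")

# small, fast dataset shared by the unit tests; the acceptance tests use the
# full study conditions (SimConfig defaults)
SMALL_CONFIG = SimConfig(
    n_clades=3,
    genes_per_chromosome=(12, 12),
    gene_length=40,
    divergence=0.02,
    n_strains_per_clade=3,
    n_recombinants=1,
    n_crossovers=3,
    intra_mut_rate=1.5,
    gap_rate=1.0,
    mean_depth=60.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def dataset():
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def truth_assignment(dataset) -> CladeAssignment:
    """Clade labels and MAT types taken from the simulator's ground truth."""
    return CladeAssignment(
        labels=dict(dataset.clade_of), mat=dict(dataset.truth.true_mat)
    )
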
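import numpy as np
import pytest

from ltrdyn.simulate import SyntheticGenomeSpec, simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def detection_dataset():
    """100-kb genome, 20 planted full-length elements, 10 decoys, no genes:
    the standard structural-detection scenario."""
    spec = SyntheticGenomeSpec.detection_scenario(seed=11)
    return spec, simulate_genome(spec)


@pytest.fixture(scope="session")
def small_dataset():
    """Small, fast dataset for pipeline-level tests."""
    spec = SyntheticGenomeSpec(
        genome_length=400_000,
        lineage_counts={"Ale": 4, "Angela": 2, "Tekay": 3, "CRM": 2},
        n_genes=25, n_solo_ltr=3, n_truncated=2, max_extra_copies=1,
        seed=5)
    return spec, simulate_genome(spec)
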
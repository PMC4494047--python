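import numpy as np
import pytest
from hypothesis import settings

from strainphy import variants
from strainphy.synthetic_evolution import EvolutionConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Compact simulated collection: 3 groups of 4/3/1 strains, 60 genes."""
    cfg = EvolutionConfig(strains_per_group=(4, 3, 1), gene_count_root=60, seed=11)
    reference, annotations, assemblies, truth = simulate_dataset(cfg)
    return cfg, reference, annotations, assemblies, truth


@pytest.fixture(scope="session")
def small_snp(small_dataset):
    _, reference, _, assemblies, _ = small_dataset
    return variants.call_snps(reference, assemblies)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: groups of 10/6/1 strains, 200 genes,
    25 diagnostic SNPs injected per group."""
    cfg = EvolutionConfig(seed=101)
    reference, annotations, assemblies, truth = simulate_dataset(cfg)
    return cfg, reference, annotations, assemblies, truth


@pytest.fixture(scope="session")
def default_snp(default_dataset):
    _, reference, _, assemblies, _ = default_dataset
    return variants.call_snps(reference, assemblies)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
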
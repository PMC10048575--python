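import pytest

from exonskip.counting import effective_lengths
from exonskip.simulate import (
    SyntheticConfig,
    generate_gene_models,
    plant_es_truth,
    simulate_junction_counts,
)


@pytest.fixture(scope="session")
def lengths():
    """Default effective lengths: r=49, j=82 -> l_I=68, l_S=34."""
    return effective_lengths()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_genes=30, seed=11, group_psi=(0.3, 0.7), coverage_mean=80.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A 30-gene synthetic dataset shared across test modules."""
    synth = generate_gene_models(small_config)
    truth = plant_es_truth(synth, small_config)
    counts = simulate_junction_counts(truth, small_config)
    return synth, truth, counts
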
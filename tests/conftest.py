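import pytest

from growthnet import SimulationConfig, generate_annotation_corpus, generate_trio_cohort
from growthnet.synthetic_data import gene_universe


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-family cohort with a light background burden (fast to classify)."""
    config = SimulationConfig(n_families=60, background_variants=10, seed=11)
    variants, ped, truth = generate_trio_cohort(config)
    return config, variants, ped, truth


@pytest.fixture(scope="session")
def planted_corpus():
    """Default three-block annotation corpus with its growth list."""
    config = SimulationConfig(seed=5)
    terms, growth, blocks = generate_annotation_corpus(config)
    return config, terms, growth, blocks, gene_universe(config)
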
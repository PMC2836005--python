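import pytest

from gingerscan import pipeline, synthdata


@pytest.fixture(scope="session")
def small_sim():
    """300-kb genome with 10 undiverged Ginger1-type elements."""
    cfg = synthdata.SimulationConfig(genome_length=300_000, n_elements=10,
                                     seed=1)
    genome, truth = synthdata.generate_genome(cfg)
    return genome, truth


@pytest.fixture(scope="session")
def small_annotated(small_sim):
    genome, _truth = small_sim
    return pipeline.annotate_genome(genome)
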
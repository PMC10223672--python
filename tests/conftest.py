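import pytest

from viropan.pipeline import PipelineConfig, run_obp
from viropan.synthetic_data import SimulationConfig, simulate_dataset

# a deliberately small corpus so unit tests stay fast: two genera of three
# genomes, four core families, one genus-restricted family per genus
SMALL = SimulationConfig(
    n_genera=2,
    genomes_per_genus=(3, 3),
    n_core_families=4,
    n_genus_families=1,
    n_unique_per_genome=1.0,
    paralog_rate=0.0,
    annotation_omission_rate=0.0,
    mean_gene_len_aa=90,
    anchor_families=(0, 1),
    seed=7,
)


@pytest.fixture(scope="session")
def small_corpus():
    return simulate_dataset(SMALL)


@pytest.fixture(scope="session")
def small_genomes(small_corpus):
    return small_corpus[0]


@pytest.fixture(scope="session")
def small_truth(small_corpus):
    return small_corpus[1]


@pytest.fixture(scope="session")
def small_run(small_genomes):
    catalogue, manifest = run_obp(small_genomes, PipelineConfig(seed=5))
    return catalogue, manifest
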
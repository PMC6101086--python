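import pytest

from backsplice.kmer_index import Config
from backsplice.synthetic_data import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def config() -> Config:
    return Config()


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    # scaled-down smoke dataset: a few genes, same biology as the defaults
    return SimParams(genome_length=30_000, n_genes=8, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params)


@pytest.fixture(scope="session")
def tiny_dataset():
    # <= 5 kb, single chromosome: cheap enough for brute-force oracles
    return simulate_dataset(
        SimParams(genome_length=5_000, n_chromosomes=1, n_genes=2,
                  exons_per_gene=(4, 5), exon_length=(60, 120),
                  intron_length=(60, 150), seed=7)
    )
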
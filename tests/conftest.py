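import pytest

from phagepop.simulate import SimConfig, generate_population


@pytest.fixture(scope="session")
def small_population():
    """3 clusters x 3 genomes, compact genomes, default divergences."""
    cfg = SimConfig(
        n_clusters=3,
        genomes_per_cluster=3,
        genome_length_range=(25_000, 45_000),
        n_variable_modules=4,
        seed=42,
    )
    return cfg, generate_population(cfg)


@pytest.fixture(scope="session")
def clean_pair_population():
    """One cluster of two genomes with zero within-cluster divergence."""
    cfg = SimConfig(
        n_clusters=1,
        genomes_per_cluster=2,
        genome_length_range=(25_000, 35_000),
        n_variable_modules=3,
        within_cluster_sub_rate=0.0,
        between_cluster_sub_rate=0.01,
        seed=7,
    )
    return cfg, generate_population(cfg)
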
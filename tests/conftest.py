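import pytest
from hypothesis import HealthCheck, settings

from rhombosort import (
    HomologRanker,
    PangenomeConfig,
    build_profile,
    generate_pangenome,
    scan_genome_set,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Small pangenome for fast unit tests (not the standard study conditions).
SMALL_CONFIG = PangenomeConfig(
    n_genomes=30,
    n_yes=8,
    genes_per_genome=12,
    targets_per_yes=(1, 4),
    seed=7,
)


@pytest.fixture(scope="session")
def small_pangenome():
    return generate_pangenome(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_pangenome():
    """The standard study conditions: 200 genomes, 40 YES, 1-13 targets."""
    return generate_pangenome(PangenomeConfig(seed=1))


@pytest.fixture(scope="session")
def default_hits(default_pangenome):
    genome_set, _truth = default_pangenome
    return scan_genome_set(genome_set)


@pytest.fixture(scope="session")
def default_profile(default_pangenome, default_hits):
    genome_set, _truth = default_pangenome
    return build_profile(genome_set, default_hits, min_count=1)


@pytest.fixture(scope="session")
def default_ranker(default_pangenome):
    genome_set, _truth = default_pangenome
    return HomologRanker(genome_set)
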
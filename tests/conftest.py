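import pytest

from coretree.fixtures import SyntheticGenomeSpec, generate_genomes, write_genome_set
from coretree.search_backend import InternalBackend

# strict threshold for fixture-based pipeline tests: random (unrelated)
# fixture sequences must never chance-hit, while planted homologues score
# far above this cutoff
FIXTURE_EVALUE = 1e-10


@pytest.fixture(scope="session")
def backend():
    return InternalBackend()


@pytest.fixture(scope="session")
def small_fixture():
    """4 genomes, 5 core, 2 duplicated families, 3 accessory genes."""
    spec = SyntheticGenomeSpec(
        n_genomes=4, n_core=5, n_dup_families=2, n_accessory=3,
        protein_length=80, rng_seed=11,
    )
    genomes, truth = generate_genomes(spec)
    return spec, genomes, truth


@pytest.fixture(scope="session")
def genbank_dir(tmp_path_factory, small_fixture):
    _, genomes, _ = small_fixture
    out = tmp_path_factory.mktemp("gbk")
    write_genome_set(genomes, out, fmt="genbank")
    return out
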
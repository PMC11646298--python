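import pytest

from mitobench.synthetic_data import GenomeSpec, make_genome


@pytest.fixture(scope="session")
def genome_and_manifest():
    """One default synthetic mitogenome shared by read-only tests."""
    return make_genome(GenomeSpec(seed=3))


@pytest.fixture(scope="session")
def genome(genome_and_manifest):
    return genome_and_manifest[0]


@pytest.fixture(scope="session")
def manifest(genome_and_manifest):
    return genome_and_manifest[1]
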
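import pytest

from magcurate.simulate import simulate_genomes


@pytest.fixture(scope="session")
def small_community():
    """3 species x 2 strains, substitution-only, 20 kb genomes."""
    return simulate_genomes(
        3, 2, genome_length_bp=20_000, intra_species_ani=99.3,
        inter_species_ani_max=90.0, indel_rate=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_community_indels():
    """Same community conditions but with the default indel component."""
    return simulate_genomes(
        3, 2, genome_length_bp=20_000, intra_species_ani=99.3,
        inter_species_ani_max=90.0, seed=11,
    )
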
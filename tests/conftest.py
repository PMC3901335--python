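import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from virobench import (  # noqa: E402
    ErrorModel,
    TruthManifest,
    build_taxonomy,
    generate_genomes,
    optimal_assembly,
    profile_from_coverages,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_taxonomy():
    """4 families x 2 genera x 2 species, half viral half bacterial."""
    return build_taxonomy(4, 2, 2, viral_fraction=0.5, seed=7)


@pytest.fixture(scope="session")
def small_genomes(small_taxonomy):
    return generate_genomes(
        small_taxonomy, length_range=(3000, 5000), n_shared_functions=2, seed=8
    )


@pytest.fixture(scope="session")
def small_community(small_taxonomy, small_genomes):
    """A modest community: 16 genomes, 800 reads, optimal assembly."""
    profile = profile_from_coverages(
        {g.genome_id: 1.0 for g in small_genomes},
        {g.genome_id: len(g) for g in small_genomes},
        800,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reads = simulate_reads(small_genomes, profile, seed=9)
    manifest = TruthManifest.from_reads(reads)
    assembly = optimal_assembly(reads, small_genomes)
    return {
        "taxonomy": small_taxonomy,
        "genomes": small_genomes,
        "reads": reads,
        "manifest": manifest,
        "assembly": assembly,
    }


@pytest.fixture(scope="session")
def divergent_genomes():
    """20 mutually divergent genomes (one species per family, no shared
    segments) for classifier benchmarks."""
    tax = build_taxonomy(20, 1, 1, viral_fraction=1.0, seed=5)
    genomes = generate_genomes(
        tax, length_range=(3000, 5000), n_shared_functions=0, seed=6
    )
    return tax, genomes
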
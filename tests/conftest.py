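import pytest

from xenostroma.simulate import (
    SimulationConfig,
    generate_signature_registry,
    generate_two_species_reference,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but fully featured study configuration shared across tests."""
    return SimulationConfig(
        n_genes_per_species=60,
        seed=7,
        niche_signatures={"HSC-niche": (15, 4), "UGM-niche": (30, 5)},
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_two_species_reference(small_config)


@pytest.fixture(scope="session")
def small_experiment(small_config, small_reference):
    return simulate_experiment(small_config, small_reference.chipdef, small_reference.truth)


@pytest.fixture(scope="session")
def small_registry(small_config, small_reference):
    return generate_signature_registry(small_reference.truth, small_config)
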
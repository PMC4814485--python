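import pytest

from aqpfam.gene_inventory import load_inventory
from aqpfam.specificity_classifier import load_profiles
from aqpfam.synthetic_data import SimConfig, reference_panel, simulate_family
from aqpfam.synthetic_reference import DEFAULT_TOPOLOGY


@pytest.fixture(scope="session")
def topology():
    return DEFAULT_TOPOLOGY


@pytest.fixture(scope="session")
def inventory():
    return load_inventory()


@pytest.fixture(scope="session")
def inventory_by_name(inventory):
    return {r.name: r for r in inventory}


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def panel():
    return reference_panel()


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated family (seed 1)."""
    return simulate_family(SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def clean_sim():
    """A noise-free family: every planted residue appears verbatim."""
    return simulate_family(SimConfig(rng_seed=1, substitution_rate=0.0))
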
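import pytest

from exomirnet import SynthConfig, generate_study, make_worked_fixture


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seed 11)."""
    return generate_study(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down study for fast stage-level tests."""
    cfg = SynthConfig(
        n_mirnas=80,
        n_genes=120,
        n_rescued_down=10,
        n_rescued_up=12,
        n_consistent_down=3,
        n_consistent_up=8,
        noise_genes_per_dataset=15,
        n_decoy_sets=5,
        seed=5,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def fig3_fixture():
    return make_worked_fixture("fig3_counts")


@pytest.fixture(scope="session")
def hub_fixture():
    return make_worked_fixture("hub_union")
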
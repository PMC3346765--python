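import pytest

from glycosnv import ProteinRecord, SimulationConfig, simulate


@pytest.fixture
def toy_protein() -> ProteinRecord:
    # one sequon: N-K-S anchored at 2
    return ProteinRecord("A1", "MNKSA")


@pytest.fixture(scope="session")
def sim_dataset():
    """A 60-protein seeded dataset shared by tests that only read it."""
    return simulate(SimulationConfig(seed=20240, n_proteins=60, n_variants=150,
                                     planted_categories={"PF_PLANTED": 5.0}))
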
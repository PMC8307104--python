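import numpy as np
import pytest

from mitocompare import synthetic_data as sd


@pytest.fixture(scope="session")
def sunanensis_table():
    return sd.emit_fixture("F_sunanensis")


@pytest.fixture(scope="session")
def all_fixture_tables():
    return {name: sd.emit_fixture(name) for name in sd.FIXTURE_SPECIES}


@pytest.fixture(scope="session")
def synthetic_reference():
    """One deterministic synthetic genome on the F. sunanensis gene plan."""
    config = sd.SimulationConfig(seed=1234)
    return sd.make_reference_genome(config)


@pytest.fixture(scope="session")
def small_clade():
    """A small simulated clade (4 ingroup + 2 outgroup) for cross-module tests."""
    config = sd.SimulationConfig(
        seed=77,
        tree=sd.default_clade_tree(n_ingroup=4, n_outgroup=2,
                                   branch=0.03, stem=0.06),
        omega=0.3,
    )
    reference = sd.make_reference_genome(config)
    return sd.evolve_clade(reference, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
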
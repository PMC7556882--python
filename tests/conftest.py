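import numpy as np
import pytest

from mdasim import (
    EnergyModel,
    EvalCounter,
    MembranePreset,
    build_demixed_membrane,
    interaction_tables,
)


@pytest.fixture(scope="session")
def small_membrane():
    """A relaxed 6+6-lipid demixed membrane with its interaction tables.

    Session-scoped and treated as read-only: tests that mutate state must
    copy the system first.
    """
    preset = MembranePreset(n_a=6, n_b=6)
    system, topologies = build_demixed_membrane(preset, seed=42)
    table, elec = interaction_tables(preset)
    return preset, system, topologies, table, elec


@pytest.fixture()
def membrane_copy(small_membrane):
    """Mutable copy of the small membrane (fresh per test)."""
    import copy

    preset, system, topologies, table, elec = small_membrane
    return preset, system.copy(), copy.deepcopy(topologies), table, elec


@pytest.fixture()
def membrane_model(membrane_copy):
    preset, system, topologies, table, elec = membrane_copy
    model = EnergyModel(table, elec, topologies, counter=EvalCounter())
    return preset, system, topologies, model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
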
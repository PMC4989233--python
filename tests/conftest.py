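import numpy as np
import pytest

from refinecomplex import (EnergyModel, FixtureSpec, build_restraints,
                           detect_interface, make_reference_complex)
from refinecomplex.params import (default_tables, load_forcefield,
                                  load_rotamer_library)


@pytest.fixture(scope="session")
def forcefield():
    return load_forcefield()


@pytest.fixture(scope="session")
def library():
    return load_rotamer_library()


@pytest.fixture(scope="session")
def tables(library):
    return default_tables(library)


@pytest.fixture(scope="session")
def dimer():
    """Small packed two-chain helix complex."""
    return make_reference_complex(FixtureSpec(chain_length=10, n_chains=2,
                                              seed=1))


@pytest.fixture(scope="session")
def dimer12():
    return make_reference_complex(FixtureSpec(chain_length=12, n_chains=2,
                                              seed=3))


@pytest.fixture(scope="session")
def trimer_c3():
    return make_reference_complex(FixtureSpec(chain_length=10, n_chains=3,
                                              symmetry=3, seed=0))


@pytest.fixture(scope="session")
def dimer_model(dimer):
    iface = detect_interface(dimer)
    restraints = build_restraints(dimer, iface, protocol=2)
    return EnergyModel(dimer, restraints)


def single_atom_structure(element="C", name="CA", resname="ALA",
                          coords=None):
    """Structures made of bare CA pseudo-atoms for closed-form tests."""
    from refinecomplex.structure import ComplexStructure
    coords = np.zeros((1, 3)) if coords is None else np.asarray(coords)
    n = len(coords)
    return ComplexStructure(
        chain_ids=["A"], atom_name=[name] * n, element=[element] * n,
        chain_index=[0] * n, res_index=list(range(1, n + 1)),
        res_name=[resname] * n, coords=coords)
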
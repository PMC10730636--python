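import math

import pytest

from xtalmol.chem_tables import default_bond_classes
from xtalmol.ensemble import build_ensemble
from xtalmol.perception import Atom, Bond, ChemicalStructure, perceive
from xtalmol import fixtures


@pytest.fixture(scope="session")
def classes():
    return default_bond_classes()


@pytest.fixture(scope="session")
def benzene_desc():
    return fixtures.make_benzene()


@pytest.fixture(scope="session")
def ferrocene_desc():
    return fixtures.make_ferrocene()


@pytest.fixture(scope="session")
def benzene_structure(benzene_desc):
    return perceive(build_ensemble(benzene_desc))


@pytest.fixture(scope="session")
def ferrocene_structure(ferrocene_desc):
    return perceive(build_ensemble(ferrocene_desc))


def make_structure(specs, bonds):
    """Ad-hoc structure builder for unit tests.

    specs: list of (element, cart) or (element, cart, dict-of-atom-kwargs)
    bonds: list of (i, j, order) or (i, j, order, dict-of-bond-kwargs)
    """
    atoms = []
    for spec in specs:
        element, cart, *rest = spec
        kwargs = rest[0] if rest else {}
        atoms.append(Atom(element=element, cart=tuple(cart), **kwargs))
    bond_objs = []
    for spec in bonds:
        i, j, order, *rest = spec
        kwargs = rest[0] if rest else {}
        length = math.dist(atoms[i].cart, atoms[j].cart)
        bond_objs.append(Bond(i=i, j=j, order=order, length=length, **kwargs))
    return ChemicalStructure(atoms=atoms, bonds=bond_objs)
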
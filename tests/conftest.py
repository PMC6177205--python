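import math

import pytest

from ironmat import SystemGeometry, table1_defaults
from ironmat.synth import ToyNetworkSpec, make_toy_network


@pytest.fixture(scope="session")
def beowulf():
    return table1_defaults("beowulf")


@pytest.fixture(scope="session")
def osp():
    return table1_defaults("osp")


@pytest.fixture(scope="session")
def geometry():
    return SystemGeometry()


@pytest.fixture(scope="session")
def observed_flux():
    """Average in situ oxygen flux into the mat, mol cm^-2 h^-1."""
    return 420e-9


@pytest.fixture
def chain():
    return make_toy_network(ToyNetworkSpec(kind="chain"))


@pytest.fixture
def diamond():
    return make_toy_network(ToyNetworkSpec(kind="diamond"))


@pytest.fixture
def autotroph_net():
    return make_toy_network(ToyNetworkSpec(kind="autotroph_fixture"))


@pytest.fixture(scope="session")
def sbml_file(tmp_path_factory):
    """Small synthetic SBML model (linear chain) written with libsbml."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel("toy")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    for sid, boundary in [("Aext", True), ("A", False), ("B", False), ("Bext", True)]:
        sp = model.createSpecies()
        sp.setId(sid)
        sp.setCompartment("c")
        sp.setBoundaryCondition(boundary)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
    def add_rxn(rid, reactants, products, rev=False):
        rx = model.createReaction()
        rx.setId(rid)
        rx.setReversible(rev)
        rx.setFast(False)
        for s, st in reactants:
            ref = rx.createReactant()
            ref.setSpecies(s)
            ref.setStoichiometry(st)
            ref.setConstant(True)
        for s, st in products:
            ref = rx.createProduct()
            ref.setSpecies(s)
            ref.setStoichiometry(st)
            ref.setConstant(True)
    add_rxn("R_in", [("Aext", 1.0)], [("A", 1.0)])
    add_rxn("biomass", [("A", 1.0)], [("B", 1.0)])
    add_rxn("R_out", [("B", 1.0)], [("Bext", 1.0)])
    path = tmp_path_factory.mktemp("sbml") / "toy.xml"
    libsbml.writeSBMLToFile(doc, str(path))
    return path
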
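import numpy as np
import pytest

from dosim import (Geometry, MaterialLibrary, SimulationConfig, build_mesh,
                   default_rule_base)
from dosim.fem import ElementMaterials

PRONY_G = (0.396, 0.542)
PRONY_TAU = (10.775, 977.88)


@pytest.fixture(scope="session")
def library():
    return MaterialLibrary()


@pytest.fixture(scope="session")
def rules():
    return default_rule_base()


@pytest.fixture()
def annulus_mesh():
    """A 15 mm tall callus annulus (no fragments), 1 mm elements."""
    return build_mesh(Geometry(12, 16, 15.0, 0.0, 15.0), 1.0)


@pytest.fixture()
def single_element_mesh():
    """One 1 mm layer of the callus annulus (2 radial x 4 axial elements)."""
    return build_mesh(Geometry(12, 16, 1.0, 0.0, 1.0), 1.0)


def elastic_materials(mesh, E=10.0, nu=0.3):
    n = mesh.n_elements
    return ElementMaterials(E=np.full(n, E), nu=np.full(n, nu),
                            soft=np.zeros(n), g_base=PRONY_G,
                            tau_base=PRONY_TAU)


def viscoelastic_materials(mesh, E=3.0, nu=0.3, g=PRONY_G, tau=PRONY_TAU,
                           relax_bulk=False):
    n = mesh.n_elements
    return ElementMaterials(E=np.full(n, E), nu=np.full(n, nu),
                            soft=np.ones(n), g_base=g, tau_base=tau,
                            relax_bulk=relax_bulk)


@pytest.fixture(scope="session")
def smoke_result():
    """A complete coarse-mesh run of the control protocol (shared)."""
    from dosim import run
    cfg = SimulationConfig(element_size=1.0, end_day=25)
    return run(cfg)
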
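import numpy as np
import pytest

from egostretch import EGOOptions, relax
from egostretch.builders import (
    OligomerBuildSpec,
    build_galacturonic_monomer,
    build_oligomer,
    build_pyranose_ring,
)
from egostretch.toyff import toy_ff_build


@pytest.fixture(scope="session")
def toy_ring():
    """Minimal anchored pyranose-like ring + its toy force field."""
    mol, topo = build_pyranose_ring("4C1")
    model = toy_ff_build(mol, topo)
    return mol, topo, model


@pytest.fixture(scope="session")
def relaxed_ring(toy_ring):
    """The toy ring relaxed to its chair minimum at zero force."""
    mol, topo, model = toy_ring
    result = relax(mol, model)
    assert result.converged
    return result.molecule, topo, model


@pytest.fixture(scope="session")
def monomer():
    mol, topo = build_galacturonic_monomer("4C1")
    return mol, topo


@pytest.fixture(scope="session")
def dimer():
    return build_oligomer(OligomerBuildSpec(n_units=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
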
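"""Synthetic structure generator: rings, monomers, oligomers, perturbation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from egostretch.builders import (
    OligomerBuildSpec,
    RingBuildSpec,
    build_galacturonic_monomer,
    build_oligomer,
    build_pyranose_ring,
    build_ring_from_pucker,
    glycosidic_quadruples,
    min_nonbonded_distance,
    perturb,
)
from egostretch.engine import relax
from egostretch.io import read_structure, write_structure
from egostretch.mol import dihedral, distance, measure_unit_lengths
from egostretch.pucker import puckering_coordinates
from egostretch.toyff import toy_ff_build


class TestRingFromPucker:
    @pytest.mark.parametrize("theta", [0.0, 45.0, 90.0, 135.0, 180.0])
    @pytest.mark.parametrize("phi", [0.0, 100.0, 250.0])
    def test_round_trip_grid(self, theta, phi):
        ring = build_ring_from_pucker(RingBuildSpec(Q=0.57, theta=theta, phi=phi))
        state = puckering_coordinates(ring, range(6))
        assert state.Q == pytest.approx(0.57, abs=1e-6)
        assert state.theta == pytest.approx(theta, abs=1e-5)
        if 1e-4 < theta < 180 - 1e-4:  # phi undefined at the poles
            assert state.phi == pytest.approx(phi, abs=1e-4)

    @given(
        theta=st.floats(5.0, 175.0),
        phi=st.floats(0.0, 359.0),
        Q=st.floats(0.3, 0.8),
    )
    @settings(max_examples=15, deadline=None)
    def test_round_trip_property(self, theta, phi, Q):
        ring = build_ring_from_pucker(RingBuildSpec(Q=Q, theta=theta, phi=phi))
        state = puckering_coordinates(ring, range(6))
        assert state.Q == pytest.approx(Q, abs=1e-6)
        assert state.theta == pytest.approx(theta, abs=1e-4)

    def test_bond_lengths_exact(self):
        spec = RingBuildSpec(Q=0.6, theta=70, phi=33, cc_bond=1.55, co_bond=1.40)
        ring = build_ring_from_pucker(spec)
        bonds = [np.linalg.norm(ring[(k + 1) % 6] - ring[k]) for k in range(6)]
        assert bonds[0] == pytest.approx(1.40, abs=1e-6)
        assert bonds[5] == pytest.approx(1.40, abs=1e-6)
        for b in bonds[1:5]:
            assert b == pytest.approx(1.55, abs=1e-6)

    def test_planar_ring_at_zero_amplitude(self):
        ring = build_ring_from_pucker(RingBuildSpec(Q=0.0))
        state = puckering_coordinates(ring, range(6))
        assert state.planar

    def test_infeasible_amplitude_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_ring_from_pucker(RingBuildSpec(Q=2.5, theta=90, phi=0))

    def test_unknown_conformer_shortcut_rejected(self):
        with pytest.raises(ValueError, match="unknown conformer"):
            RingBuildSpec(conformer="7C3")


class TestMonomer:
    def test_atom_and_bond_counts(self, monomer):
        mol, _ = monomer
        assert mol.n_atoms == 23  # C6H10O7
        assert len(mol.bonds) == 23  # one ring closure
        assert sorted(mol.elements.count(e) for e in "CHO") == [6, 7, 10]

    def test_anchor_oxygens_axial_on_opposite_sides(self, monomer):
        mol, topo = monomer
        ring = mol.coords[list(topo.units[0].ring)]
        centroid = ring.mean(axis=0)
        j = np.arange(6)
        rp = (ring - centroid) * np.sin(2 * np.pi * j / 6)[:, None]
        rpp = (ring - centroid) * np.cos(2 * np.pi * j / 6)[:, None]
        normal = np.cross(rp.sum(axis=0), rpp.sum(axis=0))
        normal /= np.linalg.norm(normal)
        o4, o1 = topo.anchors
        z1 = (mol.coords[o1] - centroid) @ normal
        z4 = (mol.coords[o4] - centroid) @ normal
        assert z1 * z4 < 0  # opposite sides of the mean plane
        assert min(abs(z1), abs(z4)) > 0.8  # clearly axial, not in-plane

    def test_inverted_conformer_classifies_as_built(self):
        mol, topo = build_galacturonic_monomer("1C4")
        state = puckering_coordinates(mol.coords, topo.units[0].ring)
        assert state.canonical_label == "1C4"

    def test_anionic_bookkeeping(self):
        mol, _ = build_galacturonic_monomer("4C1", anionic=True)
        assert mol.formal_charge == -1
        assert mol.n_atoms == 22


class TestOligomer:
    @pytest.mark.parametrize("n, linkages", [(2, 1), (6, 5)])
    def test_linkage_and_atom_counts(self, n, linkages):
        mol, topo = build_oligomer(OligomerBuildSpec(n_units=n))
        assert len(topo.linkages) == linkages
        assert mol.n_atoms == 23 * n - 3 * (n - 1)  # one water per linkage

    def test_requested_dihedrals_built_exactly(self):
        spec = OligomerBuildSpec(n_units=3, phi=[25.0, 10.0], psi=[-18.0, -35.0])
        mol, topo = build_oligomer(spec)
        phi_q, psi_q = glycosidic_quadruples(mol, topo)
        phis = [dihedral(mol.coords, *q) for q in phi_q]
        psis = [dihedral(mol.coords, *q) for q in psi_q]
        assert phis == pytest.approx([25.0, 10.0], abs=1e-6)
        assert psis == pytest.approx([-18.0, -35.0], abs=1e-6)

    def test_chain_is_clash_free(self):
        mol, _ = build_oligomer(OligomerBuildSpec(n_units=6))
        dmin, _ = min_nonbonded_distance(mol)
        assert dmin >= 1.0

    def test_linkage_atoms_bonded_through_glycosidic_oxygen(self, dimer):
        mol, topo = dimer
        c1, og, c4 = topo.linkages[0]
        assert mol.bonded(c1, og) and mol.bonded(og, c4)
        assert mol.elements[og] == "O"

    def test_anchors_at_chain_ends(self, dimer):
        mol, topo = dimer
        assert topo.anchors[0] == topo.units[0].o4
        assert topo.anchors[1] == topo.units[-1].o1

    def test_unresolvable_clash_reported(self):
        spec = OligomerBuildSpec(n_units=4, phi=[120.0] * 3, psi=[120.0] * 3)
        with pytest.raises(ValueError, match="clash"):
            build_oligomer(spec)


class TestPerturb:
    def test_zero_amplitude_is_identity(self, monomer):
        mol, _ = monomer
        assert np.array_equal(perturb(mol, 0.0, 7).coords, mol.coords)

    def test_same_seed_reproducible(self, monomer):
        mol, _ = monomer
        a = perturb(mol, 0.1, 42).coords
        b = perturb(mol, 0.1, 42).coords
        assert np.array_equal(a, b)
        c = perturb(mol, 0.1, 43).coords
        assert not np.array_equal(a, c)

    def test_displacement_bounded(self, monomer):
        mol, _ = monomer
        moved = perturb(mol, 0.05, 3)
        assert np.abs(moved.coords - mol.coords).max() <= 0.05

    def test_perturbed_chair_relaxes_back_to_chair(self, toy_ring):
        mol, topo, model = toy_ring
        res = relax(perturb(mol, 0.05, 11), model)
        assert res.converged
        state = puckering_coordinates(res.molecule.coords, topo.units[0].ring)
        assert state.canonical_label == "4C1"


class TestFixtureRoundTrips:
    @pytest.mark.parametrize("fmt", ["xyz", "pdb"])
    def test_oligomer_survives_file_round_trip(self, tmp_path, dimer, fmt):
        mol, _ = dimer
        path = str(tmp_path / f"dimer.{fmt}")
        write_structure(path, mol)
        back = read_structure(path)
        assert back.elements == mol.elements
        assert np.abs(back.coords - mol.coords).max() < 1e-3

    def test_characteristic_conformer_lengths(self):
        """Anchor O–O distances of the four key conformers fall in the
        characteristic chair/boat bands used by the length-bin labels."""
        expected = {"4C1": 4.5, "1C4": 5.5, "2SO": 5.1, "5S1": 4.3}
        for conf, centre in expected.items():
            mol, topo = build_galacturonic_monomer(conf)
            L = distance(mol.coords, *topo.anchors)
            assert abs(L - centre) <= 0.25, f"{conf}: {L:.3f} vs {centre}"
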
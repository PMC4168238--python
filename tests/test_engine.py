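"""Pulling engine: force vectors, effective surface, optimizer, vibrations."""

import numpy as np
import pytest

from egostretch.backends import SpringModel
from egostretch.engine import (
    EGOOptions,
    PullSpec,
    effective_energy,
    effective_gradient,
    external_force_vectors,
    optimize_enforced,
    relax,
    vibrational_stability,
)
from egostretch.mol import Molecule
from egostretch.units import (
    AMU_TO_KG,
    ANGSTROM_TO_BOHR,
    HARTREE_TO_JOULE,
    SPEED_OF_LIGHT_CM_S,
)


def spring_dimer(k=1.0, r0=1.5, start=None):
    mol = Molecule(
        ["O", "O"], start if start is not None else [[0, 0, 0], [1.1, 0.4, -0.3]],
        [(0, 1, 1.0)],
    )
    return mol, SpringModel([(0, 1, k, r0)])


class TestExternalForces:
    def test_zero_force_gives_zero_vectors(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 1, 0]])
        f = external_force_vectors(coords, PullSpec(0, 1, 0.0))
        assert np.all(f == 0)

    def test_collinear_pair_along_x(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        f = external_force_vectors(coords, PullSpec(1, 0, 0.05))
        assert f[1] == pytest.approx([0.05, 0, 0])
        assert f[0] == pytest.approx([-0.05, 0, 0])

    def test_newton_pair_zero_net_force_and_torque(self, rng):
        coords = rng.normal(size=(5, 3)) * 3
        f = external_force_vectors(coords, PullSpec(1, 3, 0.07))
        assert np.abs(f.sum(axis=0)).max() < 1e-10
        pivot = rng.normal(size=3)
        torque = np.cross(coords - pivot, f).sum(axis=0)
        assert np.abs(torque).max() < 1e-10

    def test_coincident_anchors_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincident"):
            external_force_vectors(coords, PullSpec(0, 1, 0.05))

    def test_pullspec_validation(self):
        with pytest.raises(ValueError):
            PullSpec(2, 2, 0.1)
        with pytest.raises(ValueError):
            PullSpec(0, 1, -0.1)


class TestEffectiveGradient:
    def test_zero_force_is_identity(self, rng):
        g = rng.normal(size=(4, 3))
        coords = rng.normal(size=(4, 3))
        assert np.array_equal(effective_gradient(g, coords, None), g)
        assert np.array_equal(effective_gradient(g, coords, PullSpec(0, 1, 0.0)), g)

    def test_matches_finite_differences_of_e_eff(self, rng):
        mol, model = spring_dimer()
        extra = Molecule(
            ["O", "O", "O"],
            rng.normal(size=(3, 3)) * 2,
            [(0, 1, 1.0), (1, 2, 1.0)],
        )
        model3 = SpringModel([(0, 1, 1.0, 1.4), (1, 2, 0.8, 1.6)])
        pull = PullSpec(0, 2, 0.06)
        coords = extra.coords
        e, g = model3.evaluate(coords)
        geff = effective_gradient(g, coords, pull)
        h = 1e-5
        for i in range(3):
            for ax in range(3):
                p = coords.copy()
                p[i, ax] += h
                ep = effective_energy(model3.evaluate(p)[0], p, pull)
                p[i, ax] -= 2 * h
                em = effective_energy(model3.evaluate(p)[0], p, pull)
                num = (em - ep) / (-2 * h) / ANGSTROM_TO_BOHR
                assert num == pytest.approx(geff[i, ax], abs=1e-6)

    def test_external_term_linear_in_force(self, rng):
        coords = rng.normal(size=(4, 3)) * 2
        g = rng.normal(size=(4, 3))
        d1 = g - effective_gradient(g, coords, PullSpec(0, 3, 0.03))
        d2 = g - effective_gradient(g, coords, PullSpec(0, 3, 0.06))
        assert np.allclose(d2, 2 * d1, atol=1e-14)


class TestOptimizer:
    def test_spring_dimer_analytic_pulled_minimum(self):
        k, r0, f = 1.0, 1.5, 0.05
        mol, model = spring_dimer(k, r0)
        res = optimize_enforced(mol, model, PullSpec(0, 1, f))
        assert res.converged
        d = np.linalg.norm(res.molecule.coords[0] - res.molecule.coords[1])
        assert d == pytest.approx(r0 + f * ANGSTROM_TO_BOHR / k, abs=1e-6)

    def test_zero_force_reduces_to_plain_minimization(self):
        mol, model = spring_dimer()
        e_start = model.evaluate(mol.coords)[0]
        res = optimize_enforced(mol, model, None)
        assert res.converged
        assert res.final_energy <= e_start

    def test_relax_of_pulled_dimer_returns_rest_length(self):
        mol, model = spring_dimer()
        pulled = optimize_enforced(mol, model, PullSpec(0, 1, 0.05))
        back = relax(pulled.molecule, model)
        d = np.linalg.norm(back.molecule.coords[0] - back.molecule.coords[1])
        assert d == pytest.approx(1.5, abs=1e-6)

    def test_relax_is_idempotent(self, relaxed_ring):
        mol, _, model = relaxed_ring
        opts = EGOOptions()
        again = relax(mol, model, opts)
        assert again.converged
        assert abs(again.final_energy - model.evaluate(mol.coords)[0]) < opts.tol_energy_change

    def test_effective_energy_monotone_along_trace(self, relaxed_ring):
        mol, topo, model = relaxed_ring
        res = optimize_enforced(mol, model, PullSpec(*topo.anchors, 0.07))
        e = np.array(res.trace.energy_eff)
        assert np.all(np.diff(e) <= 1e-12)

    def test_trace_cycles_strictly_increasing_from_one(self, relaxed_ring):
        mol, topo, model = relaxed_ring
        res = optimize_enforced(mol, model, PullSpec(*topo.anchors, 0.05))
        assert res.trace.cycles[0] == 1
        assert np.all(np.diff(res.trace.cycles) > 0)

    def test_deterministic_traces(self, relaxed_ring):
        mol, topo, model = relaxed_ring
        r1 = optimize_enforced(mol, model, PullSpec(*topo.anchors, 0.06))
        r2 = optimize_enforced(mol, model, PullSpec(*topo.anchors, 0.06))
        assert r1.trace.energy == r2.trace.energy
        assert np.array_equal(r1.molecule.coords, r2.molecule.coords)

    def test_extreme_force_ruptures_anchor_bond(self, relaxed_ring):
        mol, topo, model = relaxed_ring
        res = optimize_enforced(mol, model, PullSpec(*topo.anchors, 1.0))
        assert res.rupture_events, "expected a rupture far above the ladder"
        ruptured_atoms = {a for (pair, _, _) in res.rupture_events for a in pair}
        assert set(topo.anchors) & ruptured_atoms

    def test_grid_search_oracle_on_effective_minimum(self):
        # 2-coordinate reduction of the pulled dimer: the converged E_eff
        # matches a dense grid search over the pair distance
        k, r0, f = 1.2, 1.4, 0.04
        mol, model = spring_dimer(k, r0)
        res = optimize_enforced(mol, model, PullSpec(0, 1, f))
        d_grid = np.linspace(1.0, 2.5, 20001)
        e_grid = 0.5 * k * (d_grid - r0) ** 2 - f * d_grid * ANGSTROM_TO_BOHR
        assert res.trace.energy_eff[-1] == pytest.approx(e_grid.min(), abs=1e-4)


class TestVibrations:
    def test_spring_dimer_frequency_closed_form(self):
        k, r0 = 1.0, 1.5
        mol, model = spring_dimer(k, r0, start=[[0, 0, 0], [r0, 0, 0]])
        report = vibrational_stability(mol, model)
        assert report.n_rigid == 5  # linear molecule
        assert report.n_negative == 0
        assert len(report.frequencies) == 1
        mu = 15.999 / 2
        omega = np.sqrt(k * HARTREE_TO_JOULE / (1e-20 * AMU_TO_KG * mu))
        nu_expected = omega / (2 * np.pi * SPEED_OF_LIGHT_CM_S)
        assert report.nu_min == pytest.approx(nu_expected, rel=1e-3)

    def test_chair_minimum_has_no_negative_modes(self, relaxed_ring):
        mol, _, model = relaxed_ring
        report = vibrational_stability(mol, model)
        assert report.n_rigid == 6
        assert report.n_negative == 0
        assert report.nu_min > 0

    def test_off_minimum_structure_rejected(self):
        mol, model = spring_dimer(start=[[0, 0, 0], [2.5, 0, 0]])
        with pytest.raises(ValueError, match="stationary"):
            vibrational_stability(mol, model)
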
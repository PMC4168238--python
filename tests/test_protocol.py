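"""Force-ladder scans, minimal-force search, transition labelling.

The toy-ring thresholds referenced here (permanent chair inversion
between 0.08 and 0.09 au on the built-in backend) were established by a
brute-force ladder scan of the model; the tests assert the qualitative
structure, not the paper-level force values, which are backend-level
quantities.
"""

import numpy as np
import pytest

from egostretch.backends import SpringModel
from egostretch.engine import EGOOptions
from egostretch.mol import Molecule, SaccharideTopology
from egostretch.protocol import (
    ForceLadder,
    find_minimal_transition_force,
    label_transitions,
    run_stretch_relax_scan,
    unit_labels,
)
from egostretch.units import BOHR_TO_ANGSTROM


class DoubleWellModel:
    """Two-state model on a pair distance: E = a((d − c)² − b²)².

    Wells at d = c ± b.  Under a pull −f·d the inner well vanishes at
    the analytic threshold f* = 8ab³/(3√3) (in Hartree/Å).
    """

    def __init__(self, a=0.5, b=0.5, c=2.0):
        self.a, self.b, self.c = a, b, c

    @property
    def threshold_au(self) -> float:
        return 8 * self.a * self.b**3 / (3 * np.sqrt(3)) * BOHR_TO_ANGSTROM

    def evaluate(self, coords):
        dvec = coords[0] - coords[1]
        d = float(np.linalg.norm(dvec))
        x = d - self.c
        e = self.a * (x**2 - self.b**2) ** 2
        dedd = 4 * self.a * x * (x**2 - self.b**2)
        g = np.zeros_like(coords)
        g[0] = dedd * dvec / d
        g[1] = -g[0]
        return e, g * BOHR_TO_ANGSTROM


@pytest.fixture()
def two_state():
    model = DoubleWellModel()
    mol = Molecule(["O", "O"], [[0.0, 0, 0], [1.5, 0, 0]], [(0, 1, 1.0)])
    topo = SaccharideTopology(units=[], anchors=(0, 1))
    changed = lambda rec, start: rec.ok and rec.L_relaxed > model.c
    return mol, topo, model, changed


class TestForceLadder:
    def test_validation(self):
        with pytest.raises(ValueError):
            ForceLadder(0.05, 0.02, 0.01)
        with pytest.raises(ValueError):
            ForceLadder(0.02, 0.08, -0.01)
        with pytest.raises(ValueError):
            ForceLadder(0.02, 0.08, 0.005, refine_resolution=0.01)

    def test_grid_includes_both_ends(self):
        grid = ForceLadder(0.02, 0.08, 0.005).forces()
        assert grid[0] == pytest.approx(0.02)
        assert grid[-1] == pytest.approx(0.08)
        assert len(grid) == 13

    def test_degenerate_ladder_single_record(self, two_state):
        mol, topo, model, _ = two_state
        scan = run_stretch_relax_scan(
            mol, topo, model, ForceLadder(0.03, 0.03, 0.01)
        )
        assert len(scan.records) == 1


class TestScan:
    def test_sub_threshold_ladder_keeps_all_chairs(self, toy_ring):
        mol, topo, model = toy_ring
        scan = run_stretch_relax_scan(mol, topo, model, ForceLadder(0.02, 0.06, 0.01))
        assert scan.start_labels == ["4C1"]
        for rec in scan.records:
            assert rec.ok
            assert rec.labels_relaxed == ["4C1"]
        assert scan.transition_forces == []
        assert len(scan.regions) == 1

    def test_crossing_ladder_ends_in_inverted_chair(self, toy_ring):
        mol, topo, model = toy_ring
        scan = run_stretch_relax_scan(mol, topo, model, ForceLadder(0.02, 0.12, 0.01))
        assert len(scan.regions) >= 2
        assert scan.regions[-1][2] == ("1C4",)
        assert scan.transition_forces  # at least one boundary detected

    def test_stretched_length_nondecreasing_below_rupture(self, toy_ring):
        mol, topo, model = toy_ring
        scan = run_stretch_relax_scan(mol, topo, model, ForceLadder(0.02, 0.12, 0.01))
        L = [r.L_stretched for r in scan.records if r.ok]
        assert all(b - a > -1e-3 for a, b in zip(L, L[1:]))

    def test_regions_partition_scanned_range(self, toy_ring):
        mol, topo, model = toy_ring
        ladder = ForceLadder(0.02, 0.12, 0.01)
        scan = run_stretch_relax_scan(mol, topo, model, ladder)
        # contiguous, ordered, covering every converged force below rupture
        edges = [f for a, b, _ in scan.regions for f in (a, b)]
        assert edges == sorted(edges)
        covered = sum(
            1 for r in scan.records if any(a <= r.f <= b for a, b, _ in scan.regions)
        )
        assert covered == len(scan.records)

    def test_scan_determinism(self, toy_ring):
        mol, topo, model = toy_ring
        ladder = ForceLadder(0.03, 0.05, 0.01)
        s1 = run_stretch_relax_scan(mol, topo, model, ladder)
        s2 = run_stretch_relax_scan(mol, topo, model, ladder)
        assert [r.L_relaxed for r in s1.records] == [r.L_relaxed for r in s2.records]
        assert [r.energy_stretched for r in s1.records] == [
            r.energy_stretched for r in s2.records
        ]

    def test_backend_failure_flags_record_and_continues(self, toy_ring):
        mol, topo, _ = toy_ring

        class Flaky:
            def __init__(self, inner):
                self.inner = inner

            def evaluate(self, coords):
                e, g = self.inner.evaluate(coords)
                if e > 0.25:  # blows up once the pull does enough work
                    raise RuntimeError("backend failure")
                return e, g

        from egostretch.toyff import toy_ff_build

        flaky = Flaky(toy_ff_build(mol, topo))
        scan = run_stretch_relax_scan(mol, topo, flaky, ForceLadder(0.01, 0.1, 0.01))
        flags = [r.ok for r in scan.records]
        assert not all(flags)
        assert any(flags)


class TestMinimalForce:
    def test_recovers_analytic_threshold(self, two_state):
        mol, topo, model, changed = two_state
        ladder = ForceLadder(0.01, 0.1, 0.01, refine_resolution=0.001)
        res = find_minimal_transition_force(mol, topo, model, ladder, changed=changed)
        assert res.status == "found"
        assert res.force == pytest.approx(model.threshold_au, abs=ladder.refine_resolution)
        lo, hi = res.bracket
        assert hi - lo <= ladder.refine_resolution + 1e-12

    def test_refine_equal_step_returns_grid_answer(self, two_state):
        mol, topo, model, changed = two_state
        ladder = ForceLadder(0.01, 0.1, 0.01)  # refine defaults to step
        res = find_minimal_transition_force(mol, topo, model, ladder, changed=changed)
        assert res.status == "found"
        lo, hi = res.bracket
        # bracket is a ladder interval containing the true threshold
        assert lo == pytest.approx(0.05) and hi == pytest.approx(0.06)
        assert lo < model.threshold_au < hi

    def test_absent_when_ladder_below_threshold(self, two_state):
        mol, topo, model, changed = two_state
        res = find_minimal_transition_force(
            mol, topo, model, ForceLadder(0.005, 0.03, 0.005), changed=changed
        )
        assert res.status == "absent"
        assert res.force is None

    def test_unbracketed_when_ladder_starts_above_threshold(self, two_state):
        mol, topo, model, changed = two_state
        res = find_minimal_transition_force(
            mol, topo, model, ForceLadder(0.08, 0.1, 0.01), changed=changed
        )
        assert res.status == "unbracketed"
        assert res.bracket[0] == pytest.approx(0.08)


class TestTransitionLabels:
    def test_no_change_gives_all_none(self, toy_ring):
        mol, topo, model = toy_ring
        scan = run_stretch_relax_scan(mol, topo, model, ForceLadder(0.03, 0.03, 0.01))
        desc = label_transitions(scan.records[0], topo, scan.start_labels)
        assert [d.transition for d in desc] == ["none"]
        assert desc[0].position == "terminal-O4a"

    def test_above_threshold_terminal_chair_inversion(self, toy_ring):
        mol, topo, model = toy_ring
        scan = run_stretch_relax_scan(mol, topo, model, ForceLadder(0.1, 0.1, 0.01))
        desc = label_transitions(scan.records[0], topo, scan.start_labels)
        assert desc[0].transition == "4C1->1C4"
        assert not desc[0].provisional

    def test_hexamer_label_vector_length(self):
        from egostretch.builders import OligomerBuildSpec, build_oligomer

        mol, topo = build_oligomer(OligomerBuildSpec(n_units=6))
        labels = unit_labels(mol, topo)
        assert len(labels) == 6
        # positional classes follow the chain rule
        from egostretch.protocol import StretchRelaxRecord

        rec = StretchRelaxRecord(
            f=0.0, stretched=None, relaxed=None,
            labels_stretched=labels, labels_relaxed=labels,
            length_bins_relaxed=[], unit_lengths_stretched=[],
            unit_lengths_relaxed=[], L_stretched=0, L_relaxed=0,
            energy_stretched=0, energy_relaxed=0, ok=True,
        )
        desc = label_transitions(rec, topo, labels)
        assert len(desc) == 6
        assert [d.position for d in desc] == [
            "terminal-O4a", "internal", "internal", "internal", "internal",
            "terminal-O1a",
        ]
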
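"""The experiment driver: force-ladder stretch–relax scans.

The simulated pulling protocol mirrors the force-spectroscopy procedure:
the input structure is first relaxed at zero force; each ladder force is
then applied *to that same relaxed reference* (not chained from the
previous force), the stressed structure is re-optimized, relaxed again
with the force removed, and every saccharide unit is classified before
and after.  A conformational change is *permanent* when the relaxed
conformer label differs from the starting one — temporary deformations
that snap back on relaxation do not count.

:func:`find_minimal_transition_force` refines the ladder answer by
bisection between the last non-transitioning and the first
transitioning force, down to a requested resolution — the adaptive
counterpart of re-running the ladder on ever finer grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .backends import EnergyModel
from .engine import EGOOptions, EGOResult, PullSpec, optimize_enforced, relax
from .mol import Molecule, SaccharideTopology, measure_unit_lengths
from .pucker import label_by_length, puckering_coordinates

__all__ = [
    "ForceLadder",
    "StretchRelaxRecord",
    "ScanResult",
    "TransitionSearch",
    "TransitionDescriptor",
    "unit_labels",
    "run_stretch_relax_scan",
    "find_minimal_transition_force",
    "label_transitions",
]


@dataclass
class ForceLadder:
    """An ascending ladder of pulling forces (au) plus a refinement grain."""

    f_min: float
    f_max: float
    step: float
    refine_resolution: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.f_min <= self.f_max):
            raise ValueError("need 0 <= f_min <= f_max")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.refine_resolution is None:
            self.refine_resolution = self.step
        if not (0 < self.refine_resolution <= self.step):
            raise ValueError("need 0 < refine_resolution <= step")

    def forces(self) -> np.ndarray:
        n = int(round((self.f_max - self.f_min) / self.step))
        grid = self.f_min + self.step * np.arange(n + 1)
        grid = grid[grid <= self.f_max + 1e-12]
        if len(grid) == 0 or self.f_max - grid[-1] > 1e-12:
            grid = np.append(grid, self.f_max)
        return grid


@dataclass
class StretchRelaxRecord:
    """Everything measured at one ladder force."""

    f: float
    stretched: EGOResult
    relaxed: EGOResult
    labels_stretched: list[Optional[str]]
    labels_relaxed: list[Optional[str]]
    length_bins_relaxed: list[str]
    unit_lengths_stretched: list[float]
    unit_lengths_relaxed: list[float]
    L_stretched: float
    L_relaxed: float
    energy_stretched: float
    energy_relaxed: float
    ok: bool  # both optimizations converged
    error: Optional[str] = None


@dataclass
class ScanResult:
    """Full force-ladder scan: records, transitions, regions."""

    records: list[StretchRelaxRecord]
    start_labels: list[Optional[str]]
    transition_forces: list[float]
    #: (f_first, f_last, relaxed label vector) — constant-label intervals
    #: partitioning the scanned range below rupture
    regions: list[tuple[float, float, tuple]]
    rupture_force: Optional[float]
    reference: EGOResult

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "f_au": r.f,
                    "L_stretched": r.L_stretched,
                    "L_relaxed": r.L_relaxed,
                    "E_stretched": r.energy_stretched,
                    "E_relaxed": r.energy_relaxed,
                    "labels_relaxed": "|".join(str(x) for x in r.labels_relaxed),
                    "length_bins": "|".join(r.length_bins_relaxed),
                    "converged": r.ok,
                }
            )
        return pd.DataFrame(rows)


def unit_labels(
    mol_or_coords, topo: SaccharideTopology
) -> list[Optional[str]]:
    """Canonical conformer label of every unit's ring (None when planar)."""
    coords = mol_or_coords.coords if isinstance(mol_or_coords, Molecule) else mol_or_coords
    out = []
    for unit in topo.units:
        state = puckering_coordinates(coords, unit.ring)
        out.append(state.canonical_label)
    return out


def _make_record(
    f: float,
    stretched: EGOResult,
    relaxed: EGOResult,
    topo: SaccharideTopology,
) -> StretchRelaxRecord:
    lengths_s, L_s = measure_unit_lengths(stretched.molecule, topo)
    lengths_r, L_r = measure_unit_lengths(relaxed.molecule, topo)
    return StretchRelaxRecord(
        f=f,
        stretched=stretched,
        relaxed=relaxed,
        labels_stretched=unit_labels(stretched.molecule, topo),
        labels_relaxed=unit_labels(relaxed.molecule, topo),
        length_bins_relaxed=[label_by_length(d) for d in lengths_r],
        unit_lengths_stretched=lengths_s,
        unit_lengths_relaxed=lengths_r,
        L_stretched=L_s,
        L_relaxed=L_r,
        energy_stretched=stretched.final_energy,
        energy_relaxed=relaxed.final_energy,
        ok=stretched.converged and relaxed.converged,
    )


def _stretch_relax_at(
    f: float,
    base: EGOResult,
    topo: SaccharideTopology,
    model: EnergyModel,
    opts: Optional[EGOOptions],
) -> StretchRelaxRecord:
    pull = PullSpec(topo.anchors[0], topo.anchors[1], f)
    stretched = optimize_enforced(base.molecule, model, pull, opts)
    relaxed = relax(stretched.molecule, model, opts)
    return _make_record(f, stretched, relaxed, topo)


def run_stretch_relax_scan(
    mol: Molecule,
    topo: SaccharideTopology,
    model: EnergyModel,
    ladder: ForceLadder,
    opts: Optional[EGOOptions] = None,
) -> ScanResult:
    """Stretch–relax the molecule at every ladder force, ascending.

    Every force starts from the same zero-force-relaxed reference.  A
    backend failure at one force flags that record and the scan
    continues; the scan errors only if every force failed.
    """
    base = relax(mol, model, opts)
    start_labels = unit_labels(base.molecule, topo)
    records: list[StretchRelaxRecord] = []
    n_failed = 0
    for f in ladder.forces():
        try:
            rec = _stretch_relax_at(float(f), base, topo, model, opts)
        except Exception as exc:  # flagged, scan continues
            n_failed += 1
            rec = StretchRelaxRecord(
                f=float(f), stretched=None, relaxed=None,
                labels_stretched=[], labels_relaxed=[],
                length_bins_relaxed=[], unit_lengths_stretched=[],
                unit_lengths_relaxed=[], L_stretched=np.nan, L_relaxed=np.nan,
                energy_stretched=np.nan, energy_relaxed=np.nan,
                ok=False, error=str(exc),
            )
        records.append(rec)
    if records and n_failed == len(records):
        raise RuntimeError("every ladder force failed; first error: "
                           f"{records[0].error}")

    rupture_force = None
    for rec in records:
        if rec.stretched is not None and rec.stretched.rupture_events:
            rupture_force = rec.f
            break

    regions: list[tuple[float, float, tuple]] = []
    transition_forces: list[float] = []
    prev_vec = tuple(start_labels)
    for rec in records:
        if rupture_force is not None and rec.f >= rupture_force:
            break
        if rec.relaxed is None:
            continue
        vec = tuple(rec.labels_relaxed)
        if regions and vec == regions[-1][2]:
            regions[-1] = (regions[-1][0], rec.f, vec)
        else:
            regions.append((rec.f, rec.f, vec))
            if vec != prev_vec:
                transition_forces.append(rec.f)
        prev_vec = vec
    return ScanResult(
        records=records,
        start_labels=start_labels,
        transition_forces=transition_forces,
        regions=regions,
        rupture_force=rupture_force,
        reference=base,
    )


@dataclass
class TransitionSearch:
    """Outcome of the minimal-transition-force search."""

    status: str  # "found" | "absent" | "unbracketed"
    force: Optional[float]  # bracket midpoint when found
    bracket: Optional[tuple[float, float]]
    n_evaluations: int


def find_minimal_transition_force(
    mol: Molecule,
    topo: SaccharideTopology,
    model: EnergyModel,
    ladder: ForceLadder,
    opts: Optional[EGOOptions] = None,
    changed: Optional[Callable[[StretchRelaxRecord, list], bool]] = None,
) -> TransitionSearch:
    """Smallest force causing a permanent conformational change.

    Walks the ladder upward until the first transitioning force, then
    bisects the bracketing interval down to ``ladder.refine_resolution``
    and returns the bracket midpoint.  ``changed(record, start_labels)``
    may replace the default permanent-change criterion (any unit's
    relaxed label differing from its start label).  Outcomes:

    * ``found`` — bracket refined; ``force`` is the midpoint;
    * ``absent`` — no transition anywhere on the ladder;
    * ``unbracketed`` — already transitioning at ``f_min`` (the lower
      bracket edge is the ladder floor, not a verified no-change point).
    """
    if changed is None:
        changed = lambda rec, start: rec.ok and rec.labels_relaxed != start

    base = relax(mol, model, opts)
    start_labels = unit_labels(base.molecule, topo)
    n_eval = 0

    def probe(f: float) -> bool:
        nonlocal n_eval
        n_eval += 1
        rec = _stretch_relax_at(f, base, topo, model, opts)
        return bool(changed(rec, start_labels))

    f_lo: Optional[float] = None
    f_hi: Optional[float] = None
    for f in ladder.forces():
        if probe(float(f)):
            f_hi = float(f)
            break
        f_lo = float(f)
    if f_hi is None:
        return TransitionSearch("absent", None, None, n_eval)
    if f_lo is None:
        return TransitionSearch(
            "unbracketed", None, (ladder.f_min, f_hi), n_eval
        )
    while f_hi - f_lo > ladder.refine_resolution + 1e-15:
        mid = 0.5 * (f_lo + f_hi)
        if probe(mid):
            f_hi = mid
        else:
            f_lo = mid
    return TransitionSearch(
        "found", 0.5 * (f_lo + f_hi), (f_lo, f_hi), n_eval
    )


@dataclass
class TransitionDescriptor:
    """Per-unit start → relaxed conformer change."""

    unit: int
    from_label: Optional[str]
    to_label: Optional[str]
    transition: str  # e.g. "4C1->1C4" or "none"
    position: str  # terminal-O4a | terminal-O1a | internal
    provisional: bool  # relaxed structure had not converged


def label_transitions(
    record: StretchRelaxRecord,
    topo: SaccharideTopology,
    start_labels: list[Optional[str]],
) -> list[TransitionDescriptor]:
    """Per-unit transition descriptors for one stretch–relax record.

    ``position`` encodes the chain-position rule: the first unit carries
    the unbound O4ᵃ anchor, the last the O1ᵃ anchor (a monomer counts as
    the O4ᵃ-terminal case), everything else is internal.
    """
    n = topo.n_units
    if len(start_labels) != n or len(record.labels_relaxed) != n:
        raise ValueError("label vectors must have one entry per unit")
    out = []
    provisional = not record.ok
    for i in range(n):
        a, b = start_labels[i], record.labels_relaxed[i]
        trans = "none" if a == b else f"{a}->{b}"
        pos = "terminal-O4a" if i == 0 else (
            "terminal-O1a" if i == n - 1 else "internal"
        )
        out.append(TransitionDescriptor(i, a, b, trans, pos, provisional))
    return out
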
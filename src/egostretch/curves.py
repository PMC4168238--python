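"""Force–extension and optimization-history analysis.

Turns scan results into the observables a force-spectroscopy experiment
reports: the force–extension curve with its plateaux (extension jumps at
nearly constant force, the fingerprint of a conformational transition),
the energy landmarks along an optimization history (barrier crossings),
and per-cycle structural traces (length, glycosidic dihedrals, a ring
dihedral) that expose the order of events — chains first elongate by
rotating about their glycosidic linkages, then the rings flip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import EGOResult, OptimizationTrace
from .mol import SaccharideTopology, dihedral, distance
from .protocol import ScanResult

__all__ = [
    "ForceExtensionCurve",
    "PlateauSet",
    "HistoryLandmarks",
    "build_force_extension_curve",
    "detect_plateaus",
    "find_history_landmarks",
    "structural_trace",
    "plot_force_extension",
]


@dataclass
class ForceExtensionCurve:
    """(f, L) pairs from the stretched structures, forces strictly increasing."""

    forces: np.ndarray  # au
    extensions: np.ndarray  # Å
    excluded_forces: list[float]  # unconverged records left out
    source: str = ""

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        self.extensions = np.asarray(self.extensions, dtype=float)
        if len(self.forces) != len(self.extensions):
            raise ValueError("forces and extensions differ in length")
        if np.any(np.diff(self.forces) <= 0):
            raise ValueError("forces must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"f_au": self.forces, "L_angstrom": self.extensions})


@dataclass
class Plateau:
    onset_force: float
    delta_L: float
    span: tuple[int, int]  # index range [first, last] into the curve


@dataclass
class PlateauSet:
    plateaus: list[Plateau]

    def __post_init__(self) -> None:
        spans = [p.span for p in self.plateaus]
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:  # spans may touch at one curve point, never overlap
                raise ValueError("plateau spans must be disjoint and ordered")

    def __len__(self) -> int:
        return len(self.plateaus)

    def onset_forces(self) -> list[float]:
        return [p.onset_force for p in self.plateaus]


@dataclass
class HistoryLandmarks:
    """Energy extrema along an optimization history."""

    maxima: list[int]  # cycle numbers
    minima: list[int]
    barriers: list[float]  # E(max) − E(preceding landmark/start), Hartree

    @property
    def first_barrier_greater_than_second(self) -> Optional[bool]:
        if len(self.barriers) < 2:
            return None
        return self.barriers[0] > self.barriers[1]


def build_force_extension_curve(scan: ScanResult) -> ForceExtensionCurve:
    """Sorted (f, stretched L) pairs; unconverged records are excluded."""
    pts = []
    excluded = []
    for rec in scan.records:
        if rec.ok:
            pts.append((rec.f, rec.L_stretched))
        else:
            excluded.append(rec.f)
    if len(pts) < 2:
        raise ValueError(f"need >= 2 converged records, have {len(pts)}")
    pts.sort()
    f, L = zip(*pts)
    return ForceExtensionCurve(np.array(f), np.array(L), excluded)


def detect_plateaus(
    curve: ForceExtensionCurve,
    jump_threshold: float = 0.3,
    slope_window: int = 2,
) -> PlateauSet:
    """Spans where extension jumps while force barely advances.

    A plateau is a maximal run of consecutive curve segments whose
    extension jump is at least ``jump_threshold`` Å per ladder step
    (ladder step = median force spacing), provided the run's total force
    advance stays within ``slope_window`` ladder steps — an extension
    jump at nearly constant force, as opposed to ordinary elastic slope.
    Onset force = the first point of the run.
    """
    f, L = curve.forces, curve.extensions
    if len(f) < 4:
        raise ValueError("need at least 4 points to look for plateaus")
    step = float(np.median(np.diff(f)))
    jumps = np.diff(L)
    qualifies = jumps >= jump_threshold * (np.diff(f) / step)
    plateaus: list[Plateau] = []
    i = 0
    n = len(jumps)
    while i < n:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and qualifies[j + 1]
            and f[j + 2] - f[i] <= slope_window * step + 1e-12
        ):
            j += 1
        plateaus.append(Plateau(float(f[i]), float(L[j + 1] - L[i]), (i, j + 1)))
        i = j + 1
    return PlateauSet(plateaus)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(x, dtype=float)
    if window % 2 == 0:
        window += 1
    pad = window // 2
    xp = np.pad(np.asarray(x, dtype=float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")


def find_history_landmarks(
    trace: OptimizationTrace, smoothing_window: int = 3
) -> HistoryLandmarks:
    """Interior extrema of the backbone energy along the cycle axis.

    The energy series is smoothed by a centred moving average
    (``smoothing_window`` = 1 means raw extrema).  Maxima and minima
    alternate by construction; each barrier is the smoothed energy rise
    from the preceding landmark (or the series start) to the maximum.
    """
    if len(trace) < 5:
        raise ValueError("trace too short for landmark detection")
    e = _smooth(np.array(trace.energy), smoothing_window)
    cycles = np.array(trace.cycles)
    maxima: list[int] = []
    minima: list[int] = []
    kinds: list[tuple[int, str]] = []
    # strict interior extrema on the smoothed series, plateaus collapsed
    d = np.sign(np.diff(e))
    # propagate the previous non-zero slope across flat segments
    for k in range(1, len(d)):
        if d[k] == 0:
            d[k] = d[k - 1]
    for k in range(1, len(d)):
        if d[k - 1] > 0 and d[k] < 0:
            maxima.append(int(cycles[k]))
            kinds.append((k, "max"))
        elif d[k - 1] < 0 and d[k] > 0:
            minima.append(int(cycles[k]))
            kinds.append((k, "min"))
    barriers: list[float] = []
    prev_idx = 0
    for k, kind in kinds:
        if kind == "max":
            barriers.append(float(e[k] - e[prev_idx]))
        prev_idx = k
    return HistoryLandmarks(maxima, minima, barriers)


def structural_trace(
    result: EGOResult,
    topo: SaccharideTopology,
    phi_quadruples: Sequence[tuple[int, int, int, int]] = (),
    psi_quadruples: Sequence[tuple[int, int, int, int]] = (),
    ring_dihedral: Optional[tuple[int, int, int, int]] = None,
) -> pd.DataFrame:
    """Per-cycle table of L, selected glycosidic φ/ψ, and a ring dihedral.

    Requires the optimization to have stored its trajectory frames.  The
    default ring dihedral is O4ᵃ–C4–C3–C2 of the first unit — the ring
    torsion that jumps when the O4ᵃ-terminal ring flips.
    """
    if not result.trace.frames:
        raise ValueError("no trajectory frames stored (set store_frames=True)")
    n_atoms = result.molecule.n_atoms
    if ring_dihedral is None:
        u = topo.units[0]
        if u.o4 is None:
            raise ValueError("first unit lacks an O4-side oxygen for the ring dihedral")
        ring_dihedral = (u.o4, u.ring[4], u.ring[3], u.ring[2])
    for quad in [*phi_quadruples, *psi_quadruples, ring_dihedral]:
        for idx in quad:
            if not (0 <= idx < n_atoms):
                raise ValueError(f"observable atom {idx} out of range")
    a1, a2 = topo.anchors
    rows = []
    for cyc, frame in zip(result.trace.cycles, result.trace.frames):
        row = {"cycle": cyc, "L": distance(frame, a1, a2)}
        for k, quad in enumerate(phi_quadruples):
            row[f"phi{k + 1}"] = dihedral(frame, *quad)
        for k, quad in enumerate(psi_quadruples):
            row[f"psi{k + 1}"] = dihedral(frame, *quad)
        row["ring_dihedral"] = dihedral(frame, *ring_dihedral)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_force_extension(
    curve: ForceExtensionCurve,
    plateaus: Optional[PlateauSet] = None,
    path: Optional[str] = None,
):
    """Plot the force–extension curve, marking plateau onsets.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.forces, curve.extensions, "o-", ms=4)
    if plateaus is not None:
        for p in plateaus.plateaus:
            ax.axvline(p.onset_force, color="crimson", ls="--", lw=0.8)
    ax.set_xlabel("force (au)")
    ax.set_ylabel("anchor distance L (Å)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
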
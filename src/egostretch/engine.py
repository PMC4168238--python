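"""Geometry optimization under a constant external force pair.

The core operation: given an energy backend and a pull specification
(two anchor atoms, force magnitude *f* in atomic units), minimize the
force-modified surface

    E_eff(x) = E(x) − f · d(x),

where d is the anchor–anchor distance — constant-force pulling in
Cartesian coordinates.  A quasi-Newton (BFGS) descent with a
backtracking line search guarantees monotone decrease of E_eff; every
accepted cycle is recorded (energy, effective energy, pull distance,
gradient norms, coordinates), because the optimization *history* — not
just the endpoint — carries the mechanism: barrier crossings show up as
energy landmarks along the cycle axis.

Convergence follows the usual compound criterion of molecular geometry
optimizers: the maximum gradient component must fall below its
threshold and, in addition, either the maximum displacement of the last
step or the energy change must fall below theirs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .backends import EnergyModel
from .mol import Molecule
from .units import (
    AMU_TO_KG,
    ANGSTROM_TO_BOHR,
    HARTREE_TO_JOULE,
    SPEED_OF_LIGHT_CM_S,
)

__all__ = [
    "PullSpec",
    "EGOOptions",
    "OptimizationTrace",
    "EGOResult",
    "StabilityReport",
    "external_force_vectors",
    "effective_gradient",
    "effective_energy",
    "optimize_enforced",
    "relax",
    "vibrational_stability",
]


@dataclass(frozen=True)
class PullSpec:
    """A constant force pair: +f on ``atom_i``, −f on ``atom_j`` (au)."""

    atom_i: int
    atom_j: int
    f: float = 0.0

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("pull anchors must be two distinct atoms")
        if self.f < 0:
            raise ValueError("force magnitude must be >= 0")


@dataclass
class EGOOptions:
    """Optimizer controls.

    The convergence thresholds are the widely used defaults of quantum
    chemistry geometry optimizers: max gradient 4.5e-4 au, rms gradient
    3e-4 au, max displacement 1.8e-3 Å, energy change 1e-6 Hartree.
    ``rupture_factor`` flags any bonded pair stretched beyond that
    multiple of its reference length.
    """

    max_cycles: int = 2000
    tol_grad_max: float = 4.5e-4  # Hartree/Bohr
    tol_grad_rms: float = 3.0e-4  # Hartree/Bohr
    tol_displacement: float = 1.8e-3  # Å
    tol_energy_change: float = 1.0e-6  # Hartree
    rupture_factor: float = 2.0
    max_step: float = 0.3  # Å, trust-region cap per cycle
    store_frames: bool = True

    def __post_init__(self) -> None:
        for name in (
            "tol_grad_max",
            "tol_grad_rms",
            "tol_displacement",
            "tol_energy_change",
            "rupture_factor",
            "max_step",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass
class OptimizationTrace:
    """Per-cycle record of an enforced optimization."""

    cycles: list[int] = field(default_factory=list)
    energy: list[float] = field(default_factory=list)  # backbone E, Hartree
    energy_eff: list[float] = field(default_factory=list)  # E − f·d
    pull_distance: list[float] = field(default_factory=list)  # Å
    grad_max: list[float] = field(default_factory=list)  # Hartree/Bohr
    frames: list[np.ndarray] = field(default_factory=list)

    def append(self, cycle, e, e_eff, d, gmax, coords=None) -> None:
        if self.cycles and cycle <= self.cycles[-1]:
            raise ValueError("cycle numbers must increase strictly")
        self.cycles.append(int(cycle))
        self.energy.append(float(e))
        self.energy_eff.append(float(e_eff))
        self.pull_distance.append(float(d))
        self.grad_max.append(float(gmax))
        if coords is not None:
            self.frames.append(np.asarray(coords, dtype=float).copy())

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass
class EGOResult:
    """Outcome of one enforced optimization or relaxation."""

    molecule: Molecule
    trace: OptimizationTrace
    converged: bool
    pull: Optional[PullSpec]
    rupture_events: list[tuple[tuple[int, int], int, float]] = field(
        default_factory=list
    )
    aborted: Optional[str] = None

    @property
    def final_energy(self) -> float:
        return self.trace.energy[-1]

    @property
    def final_pull_distance(self) -> float:
        return self.trace.pull_distance[-1]


@dataclass
class StabilityReport:
    """Vibrational analysis of a stationary point."""

    nu_min: float  # cm⁻¹; negative value encodes an imaginary mode
    n_negative: int  # nontrivial modes with negative curvature
    n_rigid: int  # rigid-body modes excluded
    frequencies: np.ndarray  # all nontrivial, cm⁻¹ (signed)


# ---------------------------------------------------------------------------
# external force handling
# ---------------------------------------------------------------------------

def external_force_vectors(coords: np.ndarray, pull: PullSpec) -> np.ndarray:
    """Per-atom external force vectors (Hartree/Bohr).

    +f·û on atom_i and −f·û on atom_j with û the unit vector from j to
    i: equal, opposite, collinear forces pulling the anchors apart.
    """
    coords = np.asarray(coords, dtype=float)
    forces = np.zeros_like(coords)
    dvec = coords[pull.atom_i] - coords[pull.atom_j]
    dist = float(np.linalg.norm(dvec))
    if dist < 1e-6:
        raise ValueError("pull anchors are coincident; direction undefined")
    u = dvec / dist
    forces[pull.atom_i] = pull.f * u
    forces[pull.atom_j] = -pull.f * u
    return forces


def effective_energy(energy: float, coords: np.ndarray, pull: Optional[PullSpec]) -> float:
    """E_eff = E − f·d with d converted to Bohr (f is Hartree/Bohr)."""
    if pull is None or pull.f == 0.0:
        return float(energy)
    d = float(np.linalg.norm(coords[pull.atom_i] - coords[pull.atom_j]))
    return float(energy) - pull.f * d * ANGSTROM_TO_BOHR


def effective_gradient(
    model_gradient: np.ndarray, coords: np.ndarray, pull: Optional[PullSpec]
) -> np.ndarray:
    """Gradient of E_eff: the model gradient minus the external forces."""
    g = np.asarray(model_gradient, dtype=float)
    if pull is None or pull.f == 0.0:
        return g.copy()
    if g.shape != np.asarray(coords).shape:
        raise ValueError("gradient and coordinate shapes differ")
    return g - external_force_vectors(coords, pull)


# ---------------------------------------------------------------------------
# the optimizer
# ---------------------------------------------------------------------------

def optimize_enforced(
    mol: Molecule,
    model: EnergyModel,
    pull: Optional[PullSpec],
    opts: Optional[EGOOptions] = None,
) -> EGOResult:
    """Minimize E_eff = E − f·d by BFGS with backtracking line search.

    Descent is monotone in E_eff; each accepted cycle appends one trace
    entry.  Rupture events (bonded pair beyond ``rupture_factor`` × its
    reference length) are logged and optimization continues.  A
    non-finite energy aborts with the diagnostic trace collected so far.
    """
    opts = opts or EGOOptions()
    n = mol.n_atoms
    x = mol.coords.astype(float).ravel().copy()
    trace = OptimizationTrace()
    rupture_events: list[tuple[tuple[int, int], int, float]] = []
    ruptured: set[tuple[int, int]] = set()
    reference = _bond_reference(mol, model)

    def eval_all(xv: np.ndarray):
        coords = xv.reshape(n, 3)
        e, g = model.evaluate(coords)
        e_eff = effective_energy(e, coords, pull)
        g_eff = effective_gradient(g, coords, pull)  # Hartree/Bohr
        return e, e_eff, g_eff

    e, e_eff, g_eff = eval_all(x)
    if not np.isfinite(e):
        return EGOResult(mol.copy(), trace, False, pull, aborted="non-finite energy at start")

    H = np.eye(3 * n)  # inverse-Hessian approximation
    converged = False
    aborted = None
    g_flat = g_eff.ravel() * ANGSTROM_TO_BOHR  # Hartree/Å for stepping
    prev_e_eff = None
    disp_max = np.inf

    for cycle in range(1, opts.max_cycles + 1):
        coords = x.reshape(n, 3)
        d_pull = (
            float(np.linalg.norm(coords[pull.atom_i] - coords[pull.atom_j]))
            if pull is not None
            else 0.0
        )
        gmax = float(np.abs(g_eff).max())
        grms = float(np.sqrt(np.mean(g_eff**2)))
        trace.append(
            cycle, e, e_eff, d_pull, gmax, coords if opts.store_frames else None
        )
        _check_rupture(coords, reference, opts.rupture_factor, cycle, rupture_events, ruptured)

        de = abs(e_eff - prev_e_eff) if prev_e_eff is not None else np.inf
        if gmax <= opts.tol_grad_max and grms <= opts.tol_grad_rms and (
            disp_max <= opts.tol_displacement or de <= opts.tol_energy_change
        ):
            converged = True
            break
        prev_e_eff = e_eff

        p = -H @ g_flat
        if p @ g_flat >= 0:  # lost positive-definiteness: reset
            H = np.eye(3 * n)
            p = -g_flat
        pmax = np.abs(p).max()
        if pmax > opts.max_step:
            p *= opts.max_step / pmax

        # backtracking line search on E_eff (Armijo)
        t = 1.0
        slope = float(p @ g_flat)
        accepted = False
        for _ in range(40):
            x_new = x + t * p
            e_new, e_eff_new, g_eff_new = eval_all(x_new)
            if not np.isfinite(e_new):
                t *= 0.5
                continue
            if e_eff_new <= e_eff + 1e-4 * t * slope:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            if gmax <= opts.tol_grad_max and grms <= opts.tol_grad_rms:
                converged = True  # stationary to precision; no downhill left
            else:
                aborted = "line search failed to reduce E_eff"
            break

        s = x_new - x
        g_new_flat = g_eff_new.ravel() * ANGSTROM_TO_BOHR
        y = g_new_flat - g_flat
        sy = float(s @ y)
        if sy > 1e-12:
            rho = 1.0 / sy
            I = np.eye(3 * n)
            V = I - rho * np.outer(s, y)
            H = V @ H @ V.T + rho * np.outer(s, s)
        disp_max = float(np.abs(s).max())
        x, e, e_eff, g_eff, g_flat = x_new, e_new, e_eff_new, g_eff_new, g_new_flat
    else:
        aborted = None  # ran out of cycles; converged stays False

    if not np.isfinite(e):
        aborted = aborted or "non-finite energy"

    final = mol.with_coords(x.reshape(n, 3))
    return EGOResult(final, trace, converged, pull, rupture_events, aborted)


def relax(
    mol: Molecule, model: EnergyModel, opts: Optional[EGOOptions] = None
) -> EGOResult:
    """Re-optimize with the external forces removed (f = 0)."""
    return optimize_enforced(mol, model, None, opts)


def _bond_reference(mol: Molecule, model: EnergyModel) -> dict[tuple[int, int], float]:
    """Reference lengths for rupture detection.

    The backend's own equilibrium lengths are used when it exposes them
    (the toy backend does); otherwise the starting bond lengths.
    """
    ref = getattr(model, "bond_reference", None)
    if ref:
        return dict(ref)
    coords = mol.coords
    return {
        (i, j): float(np.linalg.norm(coords[i] - coords[j]))
        for i, j, _ in mol.bonds
    }


def _check_rupture(coords, reference, factor, cycle, events, seen) -> None:
    for (i, j), r0 in reference.items():
        if (i, j) in seen:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > factor * r0:
            events.append(((i, j), cycle, d))
            seen.add((i, j))


# ---------------------------------------------------------------------------
# vibrational analysis
# ---------------------------------------------------------------------------

def vibrational_stability(
    mol: Molecule,
    model: EnergyModel,
    grad_tol: float = 4.5e-3,
    hessian_step: float = 1e-3,
    zero_eigenvalue_tol: float = 1e-8,
) -> StabilityReport:
    """Numerical Hessian → mass-weighted normal modes at a stationary point.

    The Hessian comes from central differences of the analytic gradient
    (step ``hessian_step`` Å).  Rigid-body translations/rotations are
    projected out of the mass-weighted Hessian before diagonalization:
    exactly 6 modes for a nonlinear molecule (5 for linear).  Negative
    eigenvalues are reported as negative frequencies.
    """
    coords = mol.coords.astype(float)
    n = mol.n_atoms
    e0, g0 = model.evaluate(coords)
    if float(np.abs(g0).max()) > grad_tol:
        raise ValueError(
            f"not at a stationary point: max gradient {np.abs(g0).max():.2e} au "
            f"exceeds {grad_tol:.2e}"
        )

    # Hessian in Hartree/Å² from gradients in Hartree/Bohr
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for ax in range(3):
            probe = coords.copy()
            probe[i, ax] += hessian_step
            _, gp = model.evaluate(probe)
            probe[i, ax] -= 2 * hessian_step
            _, gm = model.evaluate(probe)
            hess[3 * i + ax] = (
                (gp - gm).ravel() * ANGSTROM_TO_BOHR / (2 * hessian_step)
            )
    hess = 0.5 * (hess + hess.T)

    masses = mol.masses()
    m3 = np.repeat(masses, 3)
    mw = hess / np.sqrt(np.outer(m3, m3))  # Hartree/(Å² amu)

    rigid = _rigid_body_basis(coords, masses)
    n_rigid = rigid.shape[1]
    # orthonormal complement of the rigid subspace
    full = np.linalg.svd(rigid, full_matrices=True)[0]
    comp = full[:, n_rigid:]
    internal = comp.T @ mw @ comp
    eigvals = np.linalg.eigvalsh(internal)

    freqs = np.array([_eig_to_wavenumber(ev) for ev in eigvals])
    n_negative = int(np.sum(eigvals < -zero_eigenvalue_tol))
    return StabilityReport(
        nu_min=float(freqs.min(initial=np.inf) if len(freqs) else np.nan),
        n_negative=n_negative,
        n_rigid=n_rigid,
        frequencies=freqs,
    )


def _eig_to_wavenumber(ev: float) -> float:
    """Mass-weighted eigenvalue (Hartree/Å²/amu) → signed wavenumber cm⁻¹."""
    omega_sq = ev * HARTREE_TO_JOULE / (1e-20 * AMU_TO_KG)  # s⁻²
    omega = np.sqrt(abs(omega_sq))
    nu = omega / (2 * np.pi * SPEED_OF_LIGHT_CM_S)
    return float(np.sign(ev) * nu)


def _rigid_body_basis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (3N × 5 or 6)."""
    n = len(masses)
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    r = coords - com
    sq = np.sqrt(masses)
    vecs = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = sq
        vecs.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        v = np.cross(r, e) * sq[:, None]
        vecs.append(v.ravel())
    basis = np.array(vecs).T
    # orthonormalize and drop null rotations (linear molecules)
    q, s, _ = np.linalg.svd(basis, full_matrices=False)
    keep = s > 1e-8 * s.max()
    return q[:, keep]
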
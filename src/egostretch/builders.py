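"""Synthetic structure generator.

Builds every input the pipeline needs without external data: ideal
pyranose rings at arbitrary pucker, α-D-galacturonic-acid-like monomers
with axial anchor oxygens at C1/C4, and (1→4)-linked oligomers up to and
beyond the hexamer.  Geometry uses standard bond lengths and tetrahedral
substituent placement; stereochemistry is fixed to the galacto
configuration (O1 and O4 axial in the ⁴C₁ chair, O2/O3 equatorial,
carboxyl equatorial at C5) and is conserved across ring conformers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .mol import (
    Molecule,
    SaccharideTopology,
    SaccharideUnit,
    dihedral,
)
from .pucker import CANONICAL_BY_NAME, cp_components

__all__ = [
    "BOND_LENGTHS",
    "RingBuildSpec",
    "OligomerBuildSpec",
    "build_ring_from_pucker",
    "build_pyranose_ring",
    "build_galacturonic_monomer",
    "build_oligomer",
    "perturb",
    "DEFAULT_PHI",
    "DEFAULT_PSI",
    "DEFAULT_RING_AMPLITUDE",
    "AMPLITUDE_BY_CLASS",
]

#: Standard bond lengths (Å) used by every builder.
BOND_LENGTHS = {
    "C-C": 1.52,
    "C-O_ring": 1.43,
    "C-O_H": 1.42,
    "C=O": 1.21,
    "C-O_acid": 1.34,
    "O-H": 0.97,
    "C-H": 1.10,
}

#: Default total puckering amplitude (Å) by conformer class.  Chairs of
#: pyranoses cluster near 0.57 Å; boats and twist-boats relieve angle
#: strain at visibly larger amplitudes (~0.75 Å); envelopes and
#: half-chairs sit in between.
DEFAULT_RING_AMPLITUDE = 0.57
AMPLITUDE_BY_CLASS = {
    "chair": 0.57,
    "boat": 0.75,
    "skew": 0.75,
    "envelope": 0.65,
    "half-chair": 0.65,
}

#: Default glycosidic dihedrals (degrees) giving an extended, clash-free
#: helix-like (1→4) chain: φ = H1–C1–Og–C4′, ψ = C1–Og–C4′–H4′.
DEFAULT_PHI = 20.0
DEFAULT_PSI = -20.0

_GLYCOSIDIC_ANGLE = 117.0  # C1–Og–C4′, degrees
_TETRA = 109.47122063449069  # tetrahedral angle, degrees


@dataclass
class RingBuildSpec:
    """Target pucker and bond lengths for an ideal six-ring.

    Either give (Q, θ, φ) directly or a canonical-label shortcut
    (``conformer``), which overrides θ/φ with the label's ideal values.
    """

    Q: Optional[float] = None
    theta: float = 0.0
    phi: float = 0.0
    cc_bond: float = BOND_LENGTHS["C-C"]
    co_bond: float = BOND_LENGTHS["C-O_ring"]
    conformer: Optional[str] = None

    def __post_init__(self) -> None:
        if self.conformer is not None:
            try:
                label = CANONICAL_BY_NAME[self.conformer]
            except KeyError:
                raise ValueError(f"unknown conformer label {self.conformer!r}")
            self.theta = label.theta
            self.phi = label.phi
            if self.Q is None:
                self.Q = AMPLITUDE_BY_CLASS[label.klass]
        if self.Q is None:
            self.Q = DEFAULT_RING_AMPLITUDE
        if self.Q < 0:
            raise ValueError("amplitude Q must be >= 0")


@dataclass
class OligomerBuildSpec:
    """How to assemble a (1→4)-linked galacturonic oligomer."""

    n_units: int = 1
    conformers: Optional[Sequence[str]] = None  # per unit; default all 4C1
    phi: Optional[Sequence[float]] = None  # per linkage
    psi: Optional[Sequence[float]] = None
    anionic: Optional[Sequence[bool]] = None  # deprotonated carboxyl per unit
    seed: Optional[int] = None
    perturb_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        n, nl = self.n_units, self.n_units - 1
        if self.conformers is None:
            self.conformers = ["4C1"] * n
        if len(self.conformers) != n:
            raise ValueError("need one conformer per unit")
        if self.phi is None:
            self.phi = [DEFAULT_PHI] * nl
        if self.psi is None:
            self.psi = [DEFAULT_PSI] * nl
        if len(self.phi) != nl or len(self.psi) != nl:
            raise ValueError("need one (phi, psi) pair per linkage")
        if self.anionic is None:
            self.anionic = [False] * n
        if len(self.anionic) != n:
            raise ValueError("need one anionic flag per unit")


# ---------------------------------------------------------------------------
# ring construction (inverse puckering)
# ---------------------------------------------------------------------------

def _inverse_pucker_z(Q: float, theta: float, phi: float) -> np.ndarray:
    """Out-of-plane displacement pattern for a pure (Q, θ, φ) pucker."""
    th, ph = np.radians(theta), np.radians(phi)
    q2, q3 = Q * np.sin(th), Q * np.cos(th)
    j = np.arange(6)
    return np.sqrt(2.0 / 6.0) * q2 * np.cos(ph + 4 * np.pi * j / 6) + q3 * (
        (-1.0) ** j
    ) / np.sqrt(6.0)


def build_ring_from_pucker(spec: RingBuildSpec) -> np.ndarray:
    """Coordinates of a six-ring with exact bond lengths and target pucker.

    Atom order is the pyranose convention (O5, C1, C2, C3, C4, C5); the
    O5–C1 and C5–O5 bonds take the C–O length, the rest the C–C length.
    Solved as a least-squares problem: six bond-length conditions plus
    the three puckering components; a solution manifold exists for any
    feasible amplitude, and infeasible specs (Q too large for the bond
    lengths) raise.
    """
    target_bonds = np.array(
        [spec.co_bond] + [spec.cc_bond] * 4 + [spec.co_bond]
    )  # bonds (0-1), (1-2), ..., (5-0)
    th, ph = np.radians(spec.theta), np.radians(spec.phi)
    q2, q3 = spec.Q * np.sin(th), spec.Q * np.cos(th)
    target_q = np.array([q2 * np.cos(ph), q2 * np.sin(ph), q3])

    # initial guess: regular hexagon in-plane, inverse-formula z
    r0 = float(np.mean(target_bonds))
    j = np.arange(6)
    guess = np.zeros((6, 3))
    guess[:, 0] = r0 * np.cos(2 * np.pi * j / 6)
    guess[:, 1] = r0 * np.sin(2 * np.pi * j / 6)
    guess[:, 2] = _inverse_pucker_z(spec.Q, spec.theta, spec.phi)

    def residuals(x: np.ndarray) -> np.ndarray:
        c = x.reshape(6, 3)
        bond_err = [
            np.linalg.norm(c[(k + 1) % 6] - c[k]) - target_bonds[k] for k in range(6)
        ]
        q = np.array(cp_components(c, range(6)))
        return np.concatenate([bond_err, q - target_q])

    sol = least_squares(
        residuals, guess.ravel(), xtol=3e-16, ftol=3e-16, gtol=3e-16, max_nfev=2000
    )
    if np.max(np.abs(sol.fun)) > 1e-7:
        raise ValueError(
            f"infeasible ring spec (Q={spec.Q}, theta={spec.theta}, phi={spec.phi}): "
            f"residual {np.max(np.abs(sol.fun)):.2e}"
        )
    return sol.x.reshape(6, 3)


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, ang: float, tors: float
) -> np.ndarray:
    """Internal-coordinate placement: position D given A, B, C.

    ``bond`` = |C–D|, ``ang`` = angle B–C–D (deg), ``tors`` = dihedral
    A–B–C–D (deg).  The standard natural-extension construction.
    """
    ang, tors = np.radians(ang), np.radians(tors)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [
            -np.cos(ang),
            np.sin(ang) * np.cos(tors),
            -np.sin(ang) * np.sin(tors),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n

def _tetra_directions(center: np.ndarray, nb1: np.ndarray, nb2: np.ndarray):
    """The two free tetrahedral directions at a centre with two neighbours.

    Returns (d_plus, d_minus) unit vectors; ``d_plus`` lies on the
    +(u1 × u2) side of the neighbour plane.  Which physical substituent
    occupies which side is the atom's configuration and is conserved
    across ring conformers.
    """
    u1, u2 = _unit(nb1 - center), _unit(nb2 - center)
    b = -(u1 + u2)
    b = _unit(b)
    p = _unit(np.cross(u1, u2))
    alpha = np.radians(_TETRA / 2.0)
    d_plus = np.cos(alpha) * b + np.sin(alpha) * p
    d_minus = np.cos(alpha) * b - np.sin(alpha) * p
    return d_plus, d_minus


# Side (sign of the u_prev × u_next component) of the heavy substituent
# at each ring carbon, in the galacto configuration.  Calibrated once on
# the ideal 4C1 chair so that O1 and O4 are axial, O2/O3 equatorial and
# the carboxyl carbon equatorial; conserved for every other conformer.
_HEAVY_SIDE: dict[str, float] = {}


def _ring_normal(ring_coords: np.ndarray) -> np.ndarray:
    r = ring_coords - ring_coords.mean(axis=0)
    j = np.arange(6)
    rp = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    return _unit(np.cross(rp, rpp))


def _heavy_sides() -> dict[str, float]:
    """Lazily calibrate the stereochemistry table on the 4C1 reference."""
    if _HEAVY_SIDE:
        return _HEAVY_SIDE
    ring = build_ring_from_pucker(RingBuildSpec(conformer="4C1"))
    normal = _ring_normal(ring)
    # axial at each carbon = the free direction more parallel to the axis
    want_axial = {"C1": True, "C2": False, "C3": False, "C4": True, "C5": False}
    for k, name in enumerate(["C1", "C2", "C3", "C4", "C5"], start=1):
        prev_i, next_i = (k - 1) % 6, (k + 1) % 6
        d_plus, d_minus = _tetra_directions(ring[k], ring[prev_i], ring[next_i])
        plus_axial = abs(d_plus @ normal) > abs(d_minus @ normal)
        side = 1.0 if plus_axial == want_axial[name] else -1.0
        _HEAVY_SIDE[name] = side
    return _HEAVY_SIDE


def _substituent_directions(ring: np.ndarray, k: int, name: str):
    """(heavy, hydrogen) unit directions at ring carbon k (1..5)."""
    side = _heavy_sides()[name]
    prev_i, next_i = (k - 1) % 6, (k + 1) % 6
    d_plus, d_minus = _tetra_directions(ring[k], ring[prev_i], ring[next_i])
    if side > 0:
        return d_plus, d_minus
    return d_minus, d_plus


def build_pyranose_ring(
    conformer: str = "4C1", Q: Optional[float] = None, with_anchors: bool = True
) -> tuple[Molecule, SaccharideTopology]:
    """Minimal pyranose-like fixture: six-ring plus the two anchor oxygens.

    A 10-atom reduction of the monomer keeping exactly the mechanical
    degrees of freedom the pulling experiment exercises: the ring, the
    axially attached C1/C4 oxygens the forces act on, and the C1/C4
    hydrogens occupying the opposite tetrahedral slots (without them the
    anchor bonds could swing from axial to equatorial through the vacant
    position and no torque would reach the ring).
    """
    ring = build_ring_from_pucker(RingBuildSpec(Q=Q, conformer=conformer))
    elements = ["O", "C", "C", "C", "C", "C"]
    coords = [ring[i] for i in range(6)]
    bonds = [(i, (i + 1) % 6, 1.0) for i in range(6)]
    labels = {0: "u0:O5", 1: "u0:C1", 2: "u0:C2", 3: "u0:C3", 4: "u0:C4", 5: "u0:C5"}
    o1 = o4 = None
    if with_anchors:
        for k, name, lab in ((1, "C1", "O1"), (4, "C4", "O4")):
            heavy, hdir = _substituent_directions(ring, k, name)
            coords.append(ring[k] + BOND_LENGTHS["C-O_H"] * heavy)
            elements.append("O")
            bonds.append((k, len(coords) - 1, 1.0))
            labels[len(coords) - 1] = f"u0:{lab}"
            if lab == "O1":
                o1 = len(coords) - 1
            else:
                o4 = len(coords) - 1
            coords.append(ring[k] + BOND_LENGTHS["C-H"] * hdir)
            elements.append("H")
            bonds.append((k, len(coords) - 1, 1.0))
            labels[len(coords) - 1] = f"u0:H{k}"
    mol = Molecule(elements, np.array(coords), bonds, labels=labels)
    unit = SaccharideUnit(ring=(0, 1, 2, 3, 4, 5), o1=o1, o4=o4)
    topo = SaccharideTopology(units=[unit], anchors=(o4, o1) if with_anchors else (0, 0))
    return mol, topo


def build_galacturonic_monomer(
    conformer: str = "4C1",
    Q: Optional[float] = None,
    anionic: bool = False,
) -> tuple[Molecule, SaccharideTopology]:
    """A 23-atom α-D-galacturonic-acid-like unit in the given ring conformer.

    C₆H₁₀O₇ connectivity: pyranose ring (O5, C1..C5), hydroxyls at
    C1/C2/C3/C4, carboxyl at C5.  In the ⁴C₁ chair the C1 and C4
    oxygens (the anchors O1ᵃ/O4ᵃ) are axial — the galacto configuration
    that makes the glycosidic/aglycone bonds mechanical levers.  With
    ``anionic`` the carboxylic proton is removed and the formal charge
    set to −1 (bookkeeping only).
    """
    ring = build_ring_from_pucker(RingBuildSpec(Q=Q, conformer=conformer))
    elements = ["O", "C", "C", "C", "C", "C"]
    coords = [ring[i] for i in range(6)]
    bonds = [(i, (i + 1) % 6, 1.0) for i in range(6)]
    labels = {0: "u0:O5", 1: "u0:C1", 2: "u0:C2", 3: "u0:C3", 4: "u0:C4", 5: "u0:C5"}

    def add(el: str, pos: np.ndarray, bond_to: int, label: str, order: float = 1.0) -> int:
        coords.append(pos)
        elements.append(el)
        idx = len(coords) - 1
        bonds.append((bond_to, idx, order))
        labels[idx] = f"u0:{label}"
        return idx

    hydroxyl_idx: dict[str, int] = {}
    for k, cname in ((1, "C1"), (2, "C2"), (3, "C3"), (4, "C4")):
        heavy, hdir = _substituent_directions(ring, k, cname)
        o_idx = add("O", ring[k] + BOND_LENGTHS["C-O_H"] * heavy, k, f"O{k}")
        # hydroxyl H anti to the previous ring atom across the C–O bond
        h_pos = place_atom(
            ring[(k - 1) % 6], ring[k], coords[o_idx], BOND_LENGTHS["O-H"], _TETRA, 180.0
        )
        add("H", h_pos, o_idx, f"HO{k}")
        add("H", ring[k] + BOND_LENGTHS["C-H"] * hdir, k, f"H{k}")
        hydroxyl_idx[f"O{k}"] = o_idx
    # C5: carboxyl heavy substituent, ring H axial
    heavy, hdir = _substituent_directions(ring, 5, "C5")
    add("H", ring[5] + BOND_LENGTHS["C-H"] * hdir, 5, "H5")
    c6 = add("C", ring[5] + BOND_LENGTHS["C-C"] * heavy, 5, "C6")
    # planar carboxyl: sp2 oxygens at 120° off the C5–C6 axis
    o6a_pos = place_atom(ring[4], ring[5], coords[c6], BOND_LENGTHS["C=O"], 120.0, 0.0)
    o6a = add("O", o6a_pos, c6, "O6A", order=2.0)
    o6b_pos = place_atom(ring[4], ring[5], coords[c6], BOND_LENGTHS["C-O_acid"], 120.0, 180.0)
    o6b = add("O", o6b_pos, c6, "O6B")
    charge = 0
    if anionic:
        charge = -1
    else:
        h_pos = place_atom(
            ring[5], coords[c6], coords[o6b], BOND_LENGTHS["O-H"], _TETRA, 0.0
        )
        add("H", h_pos, o6b, "HO6")
    mol = Molecule(elements, np.array(coords), bonds, formal_charge=charge, labels=labels)
    unit = SaccharideUnit(
        ring=(0, 1, 2, 3, 4, 5),
        o1=hydroxyl_idx["O1"],
        o4=hydroxyl_idx["O4"],
        carboxyl=(c6, o6a, o6b),
    )
    topo = SaccharideTopology(units=[unit], anchors=(hydroxyl_idx["O4"], hydroxyl_idx["O1"]))
    topo.validate(mol)
    return mol, topo


# ---------------------------------------------------------------------------
# oligomer assembly
# ---------------------------------------------------------------------------

def _rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    u, v = _unit(u), _unit(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180° about any axis perpendicular to u
        p = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = _unit(np.cross(u, p))
        return _rodrigues(axis, np.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    return _rodrigues(axis, float(np.arctan2(s, c)))


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.asarray(axis, dtype=float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _graph_distances_upto(bonds, n_atoms: int, cutoff: int = 3) -> set[tuple[int, int]]:
    """Pairs (i<j) whose bond-graph distance is <= cutoff."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for a, b, _ in bonds:
        adj[a].add(b)
        adj[b].add(a)
    close: set[tuple[int, int]] = set()
    for start in range(n_atoms):
        frontier = {start}
        seen = {start}
        for _ in range(cutoff):
            frontier = {nb for f in frontier for nb in adj[f]} - seen
            seen |= frontier
            for j in seen:
                if j > start:
                    close.add((start, j))
    return close


def min_nonbonded_distance(mol: Molecule) -> tuple[float, tuple[int, int]]:
    """Smallest distance between atoms more than 3 bonds apart."""
    close = _graph_distances_upto(mol.bonds, mol.n_atoms)
    best, pair = np.inf, (-1, -1)
    c = mol.coords
    for i in range(mol.n_atoms):
        d = np.linalg.norm(c[i + 1 :] - c[i], axis=1)
        for off in np.argsort(d)[:8]:
            j = i + 1 + int(off)
            if (i, j) not in close and d[off] < best:
                best, pair = float(d[off]), (i, j)
    return best, pair


def _h_neighbor(mol: Molecule, idx: int) -> int:
    for nb in mol.neighbors(idx):
        if mol.elements[nb] == "H":
            return nb
    raise ValueError(f"atom {idx} has no hydrogen neighbour")


def glycosidic_quadruples(mol: Molecule, topo: SaccharideTopology):
    """φ/ψ atom quadruples per linkage: H1–C1–Og–C4′ and C1–Og–C4′–H4′."""
    phi_q, psi_q = [], []
    for c1, og, c4 in topo.linkages:
        h1 = _h_neighbor(mol, c1)
        h4 = _h_neighbor(mol, c4)
        phi_q.append((h1, c1, og, c4))
        psi_q.append((c1, og, c4, h4))
    return phi_q, psi_q


def _assemble_oligomer(spec: OligomerBuildSpec, phi, psi) -> tuple[Molecule, SaccharideTopology]:
    mono, mono_topo = build_galacturonic_monomer(
        spec.conformers[0], anionic=spec.anionic[0]
    )
    elements = list(mono.elements)
    coords = [c for c in mono.coords]
    bonds = list(mono.bonds)
    labels = dict(mono.labels or {})
    charge = mono.formal_charge
    units = [mono_topo.units[0]]
    linkages: list[tuple[int, int, int]] = []

    for i in range(1, spec.n_units):
        prev = units[-1]
        og = prev.o1
        c1_prev = prev.C1
        h1_prev = next(
            nb for nb in _neighbors_of(bonds, c1_prev) if elements[nb] == "H"
        )
        # drop the hydroxyl proton on the oxygen that becomes glycosidic
        ho = next(
            (nb for nb in _neighbors_of(bonds, og) if elements[nb] == "H"), None
        )
        if ho is not None:
            elements, coords, bonds, labels, remap = _delete_atoms(
                elements, coords, bonds, labels, [ho]
            )
            units = [_remap_unit(u, remap) for u in units]
            linkages = [tuple(remap[x] for x in ln) for ln in linkages]
            og, c1_prev, h1_prev = remap[og], remap[c1_prev], remap[h1_prev]
            prev = units[-1]

        nxt, nxt_topo = build_galacturonic_monomer(
            spec.conformers[i], anionic=spec.anionic[i]
        )
        u = nxt_topo.units[0]
        o4n, c4n = u.o4, u.C4
        glyco_len = float(np.linalg.norm(nxt.coords[c4n] - nxt.coords[o4n]))
        target = place_atom(
            np.asarray(coords[h1_prev]),
            np.asarray(coords[c1_prev]),
            np.asarray(coords[og]),
            glyco_len,
            _GLYCOSIDIC_ANGLE,
            phi[i - 1],
        )
        # rigid placement: O4' of the incoming unit lands on Og, its C4–O4
        # bond aligns with the Og→C4' direction fixed by φ
        R = _rotation_aligning(
            nxt.coords[c4n] - nxt.coords[o4n], target - np.asarray(coords[og])
        )
        moved = (nxt.coords - nxt.coords[o4n]) @ R.T + np.asarray(coords[og])
        # twist about the new Og–C4' axis to the requested ψ
        h4n = _h_neighbor(nxt, c4n)
        axis = _unit(moved[c4n] - np.asarray(coords[og]))
        cur_psi = dihedral(
            np.array(list(coords) + [moved[c4n], moved[h4n]]),
            c1_prev, og, len(coords), len(coords) + 1,
        )
        delta = np.radians(cur_psi - psi[i - 1])
        Rt = _rodrigues(axis, delta)
        moved = (moved - np.asarray(coords[og])) @ Rt.T + np.asarray(coords[og])

        # merge, dropping the incoming unit's O4 and its hydroxyl proton
        ho4n = _h_neighbor(nxt, o4n)
        keep = [k for k in range(nxt.n_atoms) if k not in (o4n, ho4n)]
        offset = len(coords)
        remap_new = {}
        for newpos, k in enumerate(keep):
            remap_new[k] = offset + newpos
            coords.append(moved[k])
            elements.append(nxt.elements[k])
            if nxt.labels and k in nxt.labels:
                labels[offset + newpos] = nxt.labels[k].replace("u0:", f"u{i}:")
        for a, b, order in nxt.bonds:
            if a in remap_new and b in remap_new:
                bonds.append((remap_new[a], remap_new[b], order))
        bonds.append((og, remap_new[c4n], 1.0))
        charge += nxt.formal_charge
        new_unit = SaccharideUnit(
            ring=tuple(remap_new[x] for x in u.ring),
            o1=remap_new[u.o1],
            o4=og,
            carboxyl=tuple(remap_new[x] for x in u.carboxyl) if u.carboxyl else None,
        )
        units.append(new_unit)
        linkages.append((c1_prev, og, remap_new[c4n]))

    mol = Molecule(elements, np.array(coords), bonds, formal_charge=charge, labels=labels)
    topo = SaccharideTopology(
        units=units, linkages=linkages, anchors=(units[0].o4, units[-1].o1)
    )
    topo.validate(mol)
    return mol, topo


def _neighbors_of(bonds, i: int) -> list[int]:
    out = []
    for a, b, _ in bonds:
        if a == i:
            out.append(b)
        elif b == i:
            out.append(a)
    return out


def _delete_atoms(elements, coords, bonds, labels, to_drop):
    keep = [k for k in range(len(elements)) if k not in set(to_drop)]
    remap = {k: p for p, k in enumerate(keep)}
    new_elements = [elements[k] for k in keep]
    new_coords = [coords[k] for k in keep]
    new_bonds = [
        (remap[a], remap[b], o) for a, b, o in bonds if a in remap and b in remap
    ]
    new_labels = {remap[k]: v for k, v in labels.items() if k in remap}
    return new_elements, new_coords, new_bonds, new_labels, remap


def _remap_unit(u: SaccharideUnit, remap) -> SaccharideUnit:
    return SaccharideUnit(
        ring=tuple(remap[x] for x in u.ring),
        o1=remap[u.o1] if u.o1 is not None else None,
        o4=remap[u.o4] if u.o4 is not None else None,
        carboxyl=tuple(remap[x] for x in u.carboxyl) if u.carboxyl else None,
    )


#: Fallback whole-chain dihedral offsets tried when a build clashes.
_CLASH_RETRIES = [(0.0, 0.0), (15.0, 0.0), (-15.0, 0.0), (0.0, 15.0), (0.0, -15.0),
                  (15.0, 15.0), (-15.0, -15.0), (30.0, 0.0), (0.0, 30.0)]

#: Hard steric floor (Å) between atoms more than 3 bonds apart.
CLASH_FLOOR = 1.0


def build_oligomer(spec: OligomerBuildSpec) -> tuple[Molecule, SaccharideTopology]:
    """A (1→4)-linked galacturonic oligomer with the requested dihedrals.

    Unit *i*'s C1 is bonded through the glycosidic oxygen to unit
    *i+1*'s C4 (each linkage condenses out one water).  If the requested
    dihedrals produce a steric clash below ``CLASH_FLOOR`` the chain is
    rebuilt with small uniform dihedral offsets and the adjustment is
    reported as a warning; an unresolvable clash raises.
    """
    last_pair = (-1, -1)
    for dphi, dpsi in _CLASH_RETRIES:
        phi = [p + dphi for p in spec.phi]
        psi = [p + dpsi for p in spec.psi]
        mol, topo = _assemble_oligomer(spec, phi, psi)
        if spec.n_units == 1:
            break
        dmin, last_pair = min_nonbonded_distance(mol)
        if dmin >= CLASH_FLOOR:
            if (dphi, dpsi) != (0.0, 0.0):
                warnings.warn(
                    f"dihedrals adjusted by ({dphi}, {dpsi})° to clear a clash",
                    stacklevel=2,
                )
            break
    else:
        raise ValueError(
            f"unresolvable steric clash between atoms {last_pair} "
            f"for the requested glycosidic dihedrals"
        )
    if spec.perturb_amplitude > 0:
        mol = perturb(mol, spec.perturb_amplitude, spec.seed or 0)
    return mol, topo


def perturb(mol: Molecule, amplitude: float, seed: int) -> Molecule:
    """Add uniform random displacements in [−amplitude, amplitude] per axis."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-amplitude, amplitude, size=mol.coords.shape)
    return mol.with_coords(mol.coords + noise)
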
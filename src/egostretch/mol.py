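"""Structure data model: molecules, saccharide topologies, basic geometry.

A :class:`Molecule` is the universal record passed between every stage of
the pipeline: elements, Cartesian coordinates in Å, an explicit bond list
and a formal charge.  :class:`SaccharideTopology` adds the sugar-specific
index bookkeeping (ring atoms per unit, glycosidic oxygens, terminal
anchor oxygens) that the pulling protocol and the pucker analysis need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ELEMENTS",
    "Molecule",
    "SaccharideUnit",
    "SaccharideTopology",
    "GlycosidicDihedrals",
    "distance",
    "angle",
    "dihedral",
    "wrap_angle",
    "measure_unit_lengths",
    "measure_glycosidic_dihedrals",
    "infer_bonds",
]


@dataclass(frozen=True)
class ElementData:
    symbol: str
    covalent_radius: float  # Å
    mass: float  # amu


# Covalent radii (Cordero et al.) and standard atomic weights for the
# elements a carbohydrate pipeline encounters.
ELEMENTS: dict[str, ElementData] = {
    "H": ElementData("H", 0.31, 1.008),
    "C": ElementData("C", 0.76, 12.011),
    "N": ElementData("N", 0.71, 14.007),
    "O": ElementData("O", 0.66, 15.999),
    "P": ElementData("P", 1.07, 30.974),
    "S": ElementData("S", 1.05, 32.06),
}

#: Bond-inference cutoff: pairs closer than this multiple of the sum of
#: covalent radii are considered bonded when a format carries no bonds.
BOND_INFERENCE_FACTOR = 1.3


def _canonical_bond(i: int, j: int, order: float = 1) -> tuple[int, int, float]:
    return (min(i, j), max(i, j), float(order))


@dataclass
class Molecule:
    """Elements + Cartesian coordinates (Å) + bonds + formal charge.

    ``bonds`` holds ``(i, j, order)`` triples with ``i < j`` after
    normalisation.  ``labels`` optionally maps atom index → role tag
    (e.g. ``"u0:C1"`` for ring carbon 1 of the first saccharide unit).
    """

    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    formal_charge: int = 0
    labels: Optional[dict[int, str]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if len(self.elements) != len(self.coords):
            raise ValueError(
                f"{len(self.elements)} elements but {len(self.coords)} coordinates"
            )
        for el in self.elements:
            if el not in ELEMENTS:
                raise ValueError(f"unknown element symbol {el!r}")
        n = len(self.elements)
        seen: set[tuple[int, int]] = set()
        norm: list[tuple[int, int, float]] = []
        for bond in self.bonds:
            i, j, order = (*bond, 1.0)[:3] if len(bond) == 2 else bond
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"bond joins atom {i} to itself")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) out of range for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm.append(_canonical_bond(i, j, order))
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def masses(self) -> np.ndarray:
        return np.array([ELEMENTS[e].mass for e in self.elements])

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def bonded(self, i: int, j: int) -> bool:
        key = (min(i, j), max(i, j))
        return any((a, b) == key for a, b, _ in self.bonds)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        return replace(self, coords=np.asarray(coords, dtype=float).copy())

    def copy(self) -> "Molecule":
        return replace(
            self,
            coords=self.coords.copy(),
            bonds=list(self.bonds),
            labels=dict(self.labels) if self.labels else None,
        )


@dataclass
class SaccharideUnit:
    """Index map of one pyranose unit.

    ``ring`` lists the six ring atoms in the fixed order
    (O5, C1, C2, C3, C4, C5); the exocyclic oxygens are the C1-side
    oxygen (glycosidic or terminal O1), the C4-side oxygen (glycosidic
    or terminal O4) and the carboxyl atoms where present.
    """

    ring: tuple[int, int, int, int, int, int]
    o1: Optional[int] = None
    o4: Optional[int] = None
    carboxyl: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if len(set(self.ring)) != 6:
            raise ValueError(f"ring must have 6 distinct atoms, got {self.ring}")

    # named accessors into the ring tuple
    @property
    def O5(self) -> int:
        return self.ring[0]

    @property
    def C1(self) -> int:
        return self.ring[1]

    @property
    def C4(self) -> int:
        return self.ring[4]


@dataclass
class SaccharideTopology:
    """Per-unit ring/oxygen index map for a (1→4)-linked oligomer.

    ``linkages`` holds ``(C1 of unit i, glycosidic O, C4 of unit i+1)``
    triples in chain order; ``anchors`` are the two terminal oxygens the
    stretching forces act on: ``(O4ᵃ, O1ᵃ)``.
    """

    units: list[SaccharideUnit]
    linkages: list[tuple[int, int, int]] = field(default_factory=list)
    anchors: tuple[int, int] = (0, 0)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def validate(self, mol: Molecule) -> None:
        """Check consistency against a molecule; raise on violation."""
        n = mol.n_atoms
        ring_atoms: set[int] = set()
        for u, unit in enumerate(self.units):
            for idx in unit.ring:
                if not (0 <= idx < n):
                    raise ValueError(f"unit {u} ring index {idx} out of range")
            ring_atoms.update(unit.ring)
        for c1, og, c4 in self.linkages:
            if not (mol.bonded(c1, og) and mol.bonded(og, c4)):
                raise ValueError(f"linkage ({c1}, {og}, {c4}) atoms not bonded")
        for a in self.anchors:
            if not (0 <= a < n):
                raise ValueError(f"anchor index {a} out of range")
            if mol.elements[a] != "O":
                raise ValueError(f"anchor atom {a} is {mol.elements[a]}, not O")
            if a in ring_atoms:
                raise ValueError(f"anchor atom {a} is a ring atom")

    def unit_flanking_oxygens(self) -> list[tuple[int, int]]:
        """Per unit, the pair of distinctive oxygens flanking it in chain order.

        For unit *i* these are the C4-side oxygen (anchor O4ᵃ for the
        first unit, glycosidic otherwise) and the C1-side oxygen
        (anchor O1ᵃ for the last unit).  Their distance is the unit's
        characteristic "length".
        """
        pairs = []
        for i, unit in enumerate(self.units):
            left = unit.o4
            right = unit.o1
            if left is None or right is None:
                raise ValueError(f"unit {i} is missing a flanking oxygen")
            pairs.append((left, right))
        return pairs


@dataclass
class GlycosidicDihedrals:
    """φ/ψ values per linkage with their atom quadruples recorded verbatim."""

    phi: list[float]
    psi: list[float]
    phi_atoms: list[tuple[int, int, int, int]]
    psi_atoms: list[tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        self.phi = [wrap_angle(a) for a in self.phi]
        self.psi = [wrap_angle(a) for a in self.psi]


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees to (−180°, 180°]."""
    a = float(a) % 360.0
    if a > 180.0:
        a -= 360.0
    if a == -180.0:
        a = 180.0
    return a


def distance(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[i] - coords[j]))


def angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral i-j-k-l in degrees, IUPAC sign convention."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError(f"degenerate dihedral: collinear atoms in ({i},{j},{k},{l})")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    return float(np.degrees(np.arctan2(y, x)))


def measure_unit_lengths(
    mol: Molecule, topo: SaccharideTopology
) -> tuple[list[float], float]:
    """Per-unit flanking O–O distances (Å) and total anchor length L.

    Returns one characteristic distance per saccharide unit — between
    the distinctive oxygens flanking the unit in chain order — plus the
    anchor-to-anchor distance ``L = |O4ᵃ − O1ᵃ|``.
    """
    topo.validate(mol)
    pairs = topo.unit_flanking_oxygens()
    lengths = [distance(mol.coords, a, b) for a, b in pairs]
    L = distance(mol.coords, *topo.anchors)
    return lengths, L


def measure_glycosidic_dihedrals(
    mol: Molecule,
    quadruples_phi: Sequence[tuple[int, int, int, int]],
    quadruples_psi: Sequence[tuple[int, int, int, int]],
) -> GlycosidicDihedrals:
    """Measure φ/ψ over explicit atom quadruples (recorded verbatim)."""
    phi = [dihedral(mol.coords, *q) for q in quadruples_phi]
    psi = [dihedral(mol.coords, *q) for q in quadruples_psi]
    return GlycosidicDihedrals(phi, psi, list(quadruples_phi), list(quadruples_psi))


def infer_bonds(elements: Sequence[str], coords: np.ndarray) -> list[tuple[int, int, float]]:
    """Infer single bonds by a covalent-radius distance cutoff.

    A pair is bonded when closer than ``BOND_INFERENCE_FACTOR`` × the sum
    of covalent radii.  Used for formats (XYZ, PDB without CONECT) that
    do not carry connectivity.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(elements)
    radii = np.array([ELEMENTS[e].covalent_radius for e in elements])
    bonds: list[tuple[int, int, float]] = []
    for i in range(n):
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        cut = BOND_INFERENCE_FACTOR * (radii[i] + radii[i + 1 :])
        for off in np.nonzero(d < cut)[0]:
            bonds.append((i, i + 1 + int(off), 1.0))
    return bonds
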
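"""Six-membered-ring conformational analysis.

Implements the standard puckering-coordinate description of a pyranose
ring: displacements of the six ring atoms from their mean plane are
condensed into an amplitude/phase triple (Q, θ, φ), which places every
geometry on a sphere whose poles are the two chairs and whose equator is
the boat/twist-boat itinerary.  Ring atoms are always taken in the order
O5, C1, C2, C3, C4, C5 (IUPAC torsion sign convention), which puts the
⁴C₁ chair of a D-sugar at θ = 0° and the inverted chair ¹C₄ at θ = 180°.

Two independent classification routes are provided:

* :func:`classify_canonical` — nearest canonical conformer on the
  (θ, φ) sphere by great-circle distance;
* :func:`decompose_torsions` — least-squares mixing coefficients of the
  observed endocyclic torsion vector in an ideal three-conformer basis
  (¹C₄-type / boat-type / skew-type), from which a label is re-derived.

A third, deliberately coarse labelling (:func:`label_by_length`) bins a
unit's flanking O–O distance into the characteristic chair / twist-boat /
inverted-chair lengths observed for stretched galacturonan units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .mol import Molecule, dihedral

__all__ = [
    "PuckerState",
    "ConformerLabel",
    "CANONICAL_CONFORMERS",
    "CANONICAL_BY_NAME",
    "endocyclic_torsions",
    "cp_components",
    "puckering_coordinates",
    "classify_canonical",
    "decompose_torsions",
    "label_by_length",
    "LENGTH_BIN_CENTERS",
]

#: Below this total amplitude (Å) a ring is reported as planar and the
#: phase angles are meaningless.
PLANARITY_FLOOR = 0.05


@dataclass
class ConformerLabel:
    """One entry of the canonical conformer itinerary."""

    name: str
    klass: str  # chair | boat | skew | envelope | half-chair
    theta: float  # degrees
    phi: float  # degrees; by convention 0 for the chairs


def _build_canonical_table() -> list[ConformerLabel]:
    table = [
        ConformerLabel("4C1", "chair", 0.0, 0.0),
        ConformerLabel("1C4", "chair", 180.0, 0.0),
    ]
    # Equator, every 30°: boats at even multiples of 60° starting at 0,
    # skews (twist-boats) interleaved.  Derived from the inverse pucker
    # construction with the O5-first atom ordering.
    boats = {0: "3,OB", 60: "B1,4", 120: "2,5B", 180: "B3,O", 240: "1,4B", 300: "B2,5"}
    skews = {30: "3S1", 90: "5S1", 150: "2SO", 210: "1S3", 270: "1S5", 330: "OS2"}
    for phi, name in sorted(boats.items()):
        table.append(ConformerLabel(name, "boat", 90.0, float(phi)))
    for phi, name in sorted(skews.items()):
        table.append(ConformerLabel(name, "skew", 90.0, float(phi)))
    # Envelopes (one atom out of the plane of the other five) at
    # θ ≈ 54.7°/125.3°; half-chairs at θ ≈ 50.8°/129.2°, interleaved.
    env_n = {0: "OE", 60: "E1", 120: "2E", 180: "E3", 240: "4E", 300: "E5"}
    env_s = {0: "3E", 60: "E4", 120: "5E", 180: "EO", 240: "1E", 300: "E2"}
    half_n = {30: "OH1", 90: "2H1", 150: "2H3", 210: "4H3", 270: "4H5", 330: "OH5"}
    half_s = {30: "3H4", 90: "5H4", 150: "5HO", 210: "1HO", 270: "1H2", 330: "3H2"}
    for phi, name in sorted(env_n.items()):
        table.append(ConformerLabel(name, "envelope", 54.7, float(phi)))
    for phi, name in sorted(env_s.items()):
        table.append(ConformerLabel(name, "envelope", 125.3, float(phi)))
    for phi, name in sorted(half_n.items()):
        table.append(ConformerLabel(name, "half-chair", 50.8, float(phi)))
    for phi, name in sorted(half_s.items()):
        table.append(ConformerLabel(name, "half-chair", 129.2, float(phi)))
    return table


CANONICAL_CONFORMERS: list[ConformerLabel] = _build_canonical_table()
CANONICAL_BY_NAME: dict[str, ConformerLabel] = {
    c.name: c for c in CANONICAL_CONFORMERS
}


@dataclass
class PuckerState:
    """Puckering amplitude/phase of one six-ring plus its classification."""

    Q: float
    theta: Optional[float]  # degrees, [0, 180]; None when planar
    phi: Optional[float]  # degrees, [0, 360); None when planar
    q2: float
    q3: float
    planar: bool
    canonical_label: Optional[str] = None
    mixing_coefficients: Optional[dict[str, float]] = None


def endocyclic_torsions(mol_or_coords, ring: Sequence[int]) -> np.ndarray:
    """The six ring torsions for consecutive atom quadruples.

    ``ring`` lists the six ring atoms in order, starting at the ring
    oxygen O5.  Torsion k is about the bond ring[k+1]–ring[k+2]
    (indices mod 6), so the first returned angle is
    O5–C1–C2–C3, matching the conventional tabulation.
    """
    coords = mol_or_coords.coords if isinstance(mol_or_coords, Molecule) else np.asarray(mol_or_coords)
    ring = list(ring)
    if len(set(ring)) != 6:
        raise ValueError(f"ring must contain 6 distinct atoms, got {ring}")
    out = []
    for k in range(6):
        i, j, l, m = (ring[k], ring[(k + 1) % 6], ring[(k + 2) % 6], ring[(k + 3) % 6])
        out.append(dihedral(coords, i, j, l, m))
    return np.array(out)


def _ring_displacements(coords: np.ndarray, ring: Sequence[int]) -> np.ndarray:
    """Out-of-plane displacements z_j relative to the puckering mean plane."""
    r = np.asarray(coords, dtype=float)[list(ring)]
    r = r - r.mean(axis=0)
    j = np.arange(6)
    rp = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("degenerate ring geometry: no defined mean plane")
    return r @ (n / nn)


def cp_components(coords, ring: Sequence[int]) -> tuple[float, float, float]:
    """Raw puckering components (q2 cos φ, q2 sin φ, q3) of a six-ring."""
    z = _ring_displacements(np.asarray(coords, dtype=float), list(ring))
    j = np.arange(6)
    c = np.sqrt(2.0 / 6.0)
    q2x = c * float(z @ np.cos(4 * np.pi * j / 6))
    q2y = -c * float(z @ np.sin(4 * np.pi * j / 6))
    q3 = float(z @ ((-1.0) ** j)) / np.sqrt(6.0)
    return q2x, q2y, q3


def puckering_coordinates(mol_or_coords, ring: Sequence[int]) -> PuckerState:
    """Amplitude/phase puckering analysis of a six-membered ring.

    Returns a :class:`PuckerState`; for an (almost) planar ring the
    phase angles are undefined and the state is flagged planar with no
    conformer label.
    """
    coords = mol_or_coords.coords if isinstance(mol_or_coords, Molecule) else np.asarray(mol_or_coords)
    ring = list(ring)
    if len(set(ring)) != 6:
        raise ValueError(f"ring must contain 6 distinct atoms, got {ring}")
    q2x, q2y, q3 = cp_components(coords, ring)
    q2 = float(np.hypot(q2x, q2y))
    Q = float(np.sqrt(q2**2 + q3**2))
    if Q < PLANARITY_FLOOR:
        return PuckerState(Q, None, None, q2, q3, planar=True)
    theta = float(np.degrees(np.arctan2(q2, q3)))
    phi = float(np.degrees(np.arctan2(q2y, q2x))) % 360.0
    if phi >= 360.0:  # guard the float edge case −ε % 360 == 360.0
        phi = 0.0
    state = PuckerState(Q, theta, phi, q2, q3, planar=False)
    state.canonical_label = classify_canonical(state).name
    return state


def _sphere_distance(theta1, phi1, theta2, phi2) -> float:
    """Great-circle distance in degrees between two (θ, φ) points."""
    t1, p1, t2, p2 = np.radians([theta1, phi1, theta2, phi2])
    c = np.sin(t1) * np.sin(t2) * np.cos(p1 - p2) + np.cos(t1) * np.cos(t2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def classify_canonical(state: PuckerState) -> ConformerLabel:
    """Nearest canonical conformer on the puckering sphere.

    Ties are broken deterministically toward lower θ, then lower φ.
    """
    if state.planar or state.theta is None:
        raise ValueError("planar ring has no canonical conformer label")
    best = min(
        CANONICAL_CONFORMERS,
        key=lambda c: (
            round(_sphere_distance(state.theta, state.phi, c.theta, c.phi), 9),
            c.theta,
            c.phi,
        ),
    )
    return best


# ---------------------------------------------------------------------------
# torsion-basis decomposition
# ---------------------------------------------------------------------------

# Ideal endocyclic torsion patterns for a unit puckering displacement,
# evaluated analytically from the inverse construction in the limit of
# the standard amplitude.  The three basis members span the pucker space:
# an inverted-chair component (pure q3 < 0) and two equator components
# 90° apart in φ (the boat ¹,⁴B at φ=240° and the skew ᴼS₂ at φ=330°).
_BASIS_NAMES = ("1C4", "1,4B", "OS2")


def _ideal_torsion_vector(name: str, Q: float = 0.57) -> np.ndarray:
    # imported here to avoid a cycle: the builder uses this module too
    from .builders import build_ring_from_pucker, RingBuildSpec

    c = CANONICAL_BY_NAME[name]
    coords = build_ring_from_pucker(RingBuildSpec(Q=Q, theta=c.theta, phi=c.phi))
    return endocyclic_torsions(coords, range(6))


_BASIS_CACHE: Optional[np.ndarray] = None


def _torsion_basis() -> np.ndarray:
    global _BASIS_CACHE
    if _BASIS_CACHE is None:
        _BASIS_CACHE = np.stack([_ideal_torsion_vector(n) for n in _BASIS_NAMES])
    return _BASIS_CACHE


def decompose_torsions(torsions: Sequence[float]) -> tuple[dict[str, float], str, float]:
    """Least-squares mix of a torsion vector in the canonical basis.

    Returns ``(coefficients, closest_label, residual)``.  The closest
    label is obtained by mapping the coefficients back to an effective
    point on the puckering sphere (each basis member is a unit vector at
    its canonical (θ, φ)) and classifying that point — an independent
    route to the same answer as :func:`classify_canonical`.
    """
    t = np.asarray(torsions, dtype=float)
    if t.shape != (6,):
        raise ValueError("expected 6 endocyclic torsions")
    basis = _torsion_basis()
    coef, *_ = np.linalg.lstsq(basis.T, t, rcond=None)
    residual = float(np.linalg.norm(basis.T @ coef - t))
    coefficients = dict(zip(_BASIS_NAMES, (float(c) for c in coef)))
    # effective puckering vector (q2x, q2y, q3) implied by the mix
    vec = np.zeros(3)
    for name, c in coefficients.items():
        lab = CANONICAL_BY_NAME[name]
        th, ph = np.radians(lab.theta), np.radians(lab.phi)
        vec += c * np.array(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )
    amp = np.linalg.norm(vec)
    if amp < 1e-9:
        raise ValueError("torsion vector has no resolvable pucker component")
    theta = float(np.degrees(np.arccos(np.clip(vec[2] / amp, -1, 1))))
    phi = float(np.degrees(np.arctan2(vec[1], vec[0]))) % 360.0
    label = classify_canonical(
        PuckerState(1.0, theta, phi, 0.0, 0.0, planar=False)
    ).name
    return coefficients, label, residual


# ---------------------------------------------------------------------------
# coarse length bins
# ---------------------------------------------------------------------------

#: Characteristic flanking O–O distances (Å) of relaxed stretched
#: galacturonan units: chair, type-1 twist-boat (⁵S₁), type-2 twist-boat
#: (²S_O), inverted chair.
LENGTH_BIN_CENTERS: dict[str, float] = {"c": 4.5, "b1": 4.3, "b2": 5.1, "ic": 5.5}

#: Tie-break priority: lower-energy conformers win an exact tie.
_BIN_PRIORITY = ("c", "ic", "b1", "b2")


def label_by_length(oo_distance: float, window: float = 0.25) -> str:
    """Bin a unit's flanking O–O distance into {c, b1, b2, ic, unassigned}.

    The nearest characteristic centre within ±``window`` Å wins; exact
    ties go to the lower-energy conformer (chair first).
    """
    if oo_distance <= 0:
        raise ValueError("distance must be positive")
    best = min(
        LENGTH_BIN_CENTERS,
        key=lambda k: (
            round(abs(oo_distance - LENGTH_BIN_CENTERS[k]), 12),
            _BIN_PRIORITY.index(k),
        ),
    )
    if abs(oo_distance - LENGTH_BIN_CENTERS[best]) <= window:
        return best
    return "unassigned"
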
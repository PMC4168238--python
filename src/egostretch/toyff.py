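"""Built-in toy molecular-mechanics backend.

A deliberately small valence force field — harmonic bonds and angles,
cosine torsions, and a soft nonbonded repulsion — whose six-ring
energetics nonetheless exhibit the conformer landscape the pulling
experiment probes: a chair global minimum, a twist-boat band of local
minima, and an inverted chair, with inversion passing through the
equatorial band.  It makes no claim of thermochemical accuracy; its job
is to let every stage of the pipeline run at desk scale with energies in
Hartree and gradients in Hartree/Bohr, like any other backend.

Endocyclic torsions get a dedicated two-term cosine profile
``c3 (1 + cos 3τ) + c1 (1 + cos τ)``: the three-fold term builds the
staggered wells at τ ≈ ±60°, the one-fold term penalises eclipsed
arrangements so that ring inversion prefers the twist-boat route.
Parameters ship in a versioned defaults file (``data/toyff-1.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .mol import Molecule, SaccharideTopology
from .units import BOHR_TO_ANGSTROM

__all__ = ["ToyFFParams", "ToyFF", "toy_ff_build", "load_default_params"]

_DEFAULTS_FILE = "toyff-1.yaml"


@dataclass
class ToyFFParams:
    """Force-field parameters; see ``data/toyff-1.yaml`` for units."""

    bond_k: dict[str, float]
    bond_r0: dict[str, float]
    angle_k: float
    theta0: dict[str, float]
    torsion_k: float
    ring_c3: float
    ring_c1: float
    nb_epsilon: float
    nb_sigma: float
    nb_min_path: int
    version: int = 1

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.bond_k.values()) or self.angle_k <= 0:
            raise ValueError("force constants must be positive")


def load_default_params() -> ToyFFParams:
    """Parameters from the versioned defaults file shipped as package data."""
    text = resources.files("egostretch.data").joinpath(_DEFAULTS_FILE).read_text()
    raw = yaml.safe_load(text)
    ff = raw["toy_ff"]
    return ToyFFParams(
        bond_k=dict(ff["bond_k"]),
        bond_r0=dict(ff["bond_r0"]),
        angle_k=float(ff["angle_k"]),
        theta0={k: float(v) for k, v in ff["theta0"].items()},
        torsion_k=float(ff["torsion_k"]),
        ring_c3=float(ff["ring_torsion"]["c3"]),
        ring_c1=float(ff["ring_torsion"]["c1"]),
        nb_epsilon=float(ff["nonbonded"]["epsilon"]),
        nb_sigma=float(ff["nonbonded"]["sigma"]),
        nb_min_path=int(ff["nonbonded"]["min_path"]),
        version=int(raw.get("version", 1)),
    )


def _bond_key(el_i: str, el_j: str, order: float) -> str:
    a, b = sorted((el_i, el_j))
    sep = "=" if order >= 2 else "-"
    return f"{a}{sep}{b}"


def _find_six_rings(mol: Molecule) -> list[tuple[int, ...]]:
    """All simple 6-cycles in the bond graph, by depth-limited DFS."""
    adj = {i: set(mol.neighbors(i)) for i in range(mol.n_atoms)}
    found: dict[frozenset, tuple[int, ...]] = {}

    def dfs(path: list[int], start: int) -> None:
        if len(path) == 6:
            if start in adj[path[-1]]:
                found.setdefault(frozenset(path), tuple(path))
            return
        for nb in sorted(adj[path[-1]]):
            if nb not in path and nb != start:
                dfs(path + [nb], start)

    for s in range(mol.n_atoms):
        dfs([s], s)
    return list(found.values())


class ToyFF:
    """Compiled toy force field for one molecule (an ``EnergyModel``)."""

    def __init__(
        self,
        mol: Molecule,
        topo: Optional[SaccharideTopology] = None,
        params: Optional[ToyFFParams] = None,
    ):
        if not mol.bonds:
            raise ValueError("toy force field needs an explicit bond list")
        self.params = p = params or load_default_params()
        self.n_atoms = mol.n_atoms

        missing: list[str] = []
        self.bond_terms: list[tuple[int, int, float, float]] = []
        for i, j, order in mol.bonds:
            key = _bond_key(mol.elements[i], mol.elements[j], order)
            if key not in p.bond_k or key not in p.bond_r0:
                missing.append(f"bond {key} ({i}-{j})")
                continue
            self.bond_terms.append((i, j, p.bond_k[key], p.bond_r0[key]))
        #: reference lengths for rupture bookkeeping, keyed (i, j) with i<j
        self.bond_reference = {(i, j): r0 for i, j, _, r0 in self.bond_terms}

        neighbors = {i: mol.neighbors(i) for i in range(mol.n_atoms)}
        self.angle_terms: list[tuple[int, int, int, float, float]] = []
        for j in range(mol.n_atoms):
            nbs = neighbors[j]
            if len(nbs) < 2:
                continue
            key = f"{mol.elements[j]}{len(nbs)}"
            if key not in p.theta0:
                missing.append(f"angle centre {key} (atom {j})")
                continue
            th0 = np.radians(p.theta0[key])
            for a in range(len(nbs)):
                for b in range(a + 1, len(nbs)):
                    self.angle_terms.append((nbs[a], j, nbs[b], p.angle_k, th0))
        if missing:
            raise ValueError("missing toy-FF parameters for: " + "; ".join(missing))

        # ring atom sets (for the endocyclic torsion profile)
        if topo is not None:
            ring_sets = [frozenset(u.ring) for u in topo.units]
        else:
            ring_sets = [frozenset(r) for r in _find_six_rings(mol)]

        # torsions: one term per quadruple around each central bond
        self.torsion_terms: list[tuple[int, int, int, int, tuple[tuple[float, float], ...]]] = []
        generic = ((p.torsion_k, 3.0),)
        ring_profile = ((p.ring_c3, 3.0), (p.ring_c1, 1.0))
        for j, k, _ in mol.bonds:
            for a in neighbors[j]:
                if a == k:
                    continue
                for d in neighbors[k]:
                    if d == j or d == a:
                        continue
                    quad = (a, j, k, d)
                    endo = any(set(quad) <= rs for rs in ring_sets)
                    self.torsion_terms.append(
                        (a, j, k, d, ring_profile if endo else generic)
                    )

        # nonbonded soft repulsion between topologically distant pairs
        close = _pairs_within(mol.bonds, mol.n_atoms, p.nb_min_path - 1)
        self.nb_pairs = [
            (i, j)
            for i in range(mol.n_atoms)
            for j in range(i + 1, mol.n_atoms)
            if (i, j) not in close
        ]

    # -- energy & analytic gradient ----------------------------------------

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        c = np.asarray(coords, dtype=float)
        if c.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords shape {(self.n_atoms, 3)}, got {c.shape}")
        energy = 0.0
        grad = np.zeros_like(c)  # Hartree/Å; converted on return

        for i, j, k, r0 in self.bond_terms:
            dvec = c[i] - c[j]
            d = float(np.linalg.norm(dvec))
            energy += 0.5 * k * (d - r0) ** 2
            g = k * (d - r0) * dvec / d
            grad[i] += g
            grad[j] -= g

        p = self.params
        for a, j, b, k, th0 in self.angle_terms:
            u = c[a] - c[j]
            v = c[b] - c[j]
            lu, lv = np.linalg.norm(u), np.linalg.norm(v)
            uh, vh = u / lu, v / lv
            cos_t = float(np.clip(uh @ vh, -1.0, 1.0))
            sin_t = float(np.sqrt(max(1.0 - cos_t * cos_t, 1e-16)))
            theta = float(np.arccos(cos_t))
            pref = k * (theta - th0)
            da = (cos_t * uh - vh) / (lu * sin_t)
            db = (cos_t * vh - uh) / (lv * sin_t)
            energy += 0.5 * k * (theta - th0) ** 2
            grad[a] += pref * da
            grad[b] += pref * db
            grad[j] -= pref * (da + db)

        for i, j, k, l, series in self.torsion_terms:
            phi, (gi, gj, gk, gl) = _dihedral_and_grad(c[i], c[j], c[k], c[l])
            dv = 0.0
            for amp, n in series:
                energy += amp * (1.0 + np.cos(n * phi))
                dv += -amp * n * np.sin(n * phi)
            grad[i] += dv * gi
            grad[j] += dv * gj
            grad[k] += dv * gk
            grad[l] += dv * gl

        eps, sigma = p.nb_epsilon, p.nb_sigma
        for i, j in self.nb_pairs:
            dvec = c[i] - c[j]
            d = float(np.linalg.norm(dvec))
            if d < sigma:
                x = 1.0 - d / sigma
                energy += eps * x * x
                g = (-2.0 * eps * x / sigma) * dvec / d
                grad[i] += g
                grad[j] -= g

        return float(energy), grad * BOHR_TO_ANGSTROM


def _dihedral_and_grad(ri, rj, rk, rl):
    """Dihedral (radians) and its Cartesian gradient, standard formulas."""
    b1 = rj - ri
    b2 = rk - rj
    b3 = rl - rk
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2)
    mm = float(m @ m)
    nn = float(n @ n)
    if mm < 1e-14 or nn < 1e-14:
        raise ValueError("degenerate torsion: three collinear atoms")
    x = float(m @ n)
    y = float(np.cross(m, b2 / lb2) @ n)
    phi = np.arctan2(y, x)
    gi = (lb2 / mm) * m
    gl = -(lb2 / nn) * n
    t1 = float(b1 @ b2) / (lb2 * lb2)
    t3 = float(b3 @ b2) / (lb2 * lb2)
    gj = -(1.0 + t1) * gi + t3 * gl
    gk = t1 * gi - (1.0 + t3) * gl
    return phi, (gi, gj, gk, gl)


def _pairs_within(bonds, n_atoms: int, cutoff: int) -> set[tuple[int, int]]:
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


def toy_ff_build(
    mol: Molecule,
    topo: Optional[SaccharideTopology] = None,
    params: Optional[ToyFFParams] = None,
) -> ToyFF:
    """Compile the toy force field for a molecule.

    ``topo`` marks which six-rings carry the endocyclic torsion profile;
    without it, six-membered cycles are detected from the bond graph.
    Raises listing every bonded pair/triple that lacks a parameter.
    """
    return ToyFF(mol, topo=topo, params=params)
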
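"""Readers and writers for XYZ (plain and multi-frame) and PDB.

Coordinates are Å in both formats.  XYZ carries no bonds, so they are
inferred by the covalent-radius cutoff; PDB CONECT records are honoured
when present and inference is the fallback.  Readers reject, rather than
silently repair, inconsistent records.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import numpy as np

from .mol import ELEMENTS, Molecule, infer_bonds

__all__ = [
    "ParseError",
    "read_structure",
    "write_structure",
    "read_xyz_frames",
    "write_xyz_frames",
]


class ParseError(ValueError):
    """Malformed structure file; message names the offending line."""


def _parse_xyz_frame(lines: list[str], start: int, path: str):
    try:
        n = int(lines[start].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"{path}:{start + 1}: expected an atom count")
    if n <= 0:
        raise ParseError(f"{path}:{start + 1}: atom count must be positive")
    comment = lines[start + 1].rstrip("\n") if start + 1 < len(lines) else ""
    elements: list[str] = []
    coords: list[list[float]] = []
    for k in range(n):
        ln = start + 2 + k
        if ln >= len(lines) or not lines[ln].strip():
            raise ParseError(
                f"{path}:{ln + 1}: declared {n} atoms but file ends at atom {k}"
            )
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{ln + 1}: expected 'El x y z'")
        el = parts[0].capitalize()
        if el not in ELEMENTS:
            raise ParseError(f"{path}:{ln + 1}: unknown element {parts[0]!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}:{ln + 1}: bad coordinate field")
        elements.append(el)
        coords.append(xyz)
    return elements, np.array(coords), comment, start + 2 + n


def read_xyz_frames(path: str) -> list[Molecule]:
    """Read all frames of a (multi-frame) XYZ file."""
    with open(path) as fh:
        lines = fh.readlines()
    frames: list[Molecule] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        elements, coords, _, pos = _parse_xyz_frame(lines, pos, path)
        frames.append(
            Molecule(elements, coords, infer_bonds(elements, coords))
        )
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


def write_xyz_frames(
    path: str, frames: Iterable[Molecule], comments: Optional[list[str]] = None
) -> None:
    frames = list(frames)
    comments = comments or [""] * len(frames)
    with open(path, "w") as fh:
        for mol, comment in zip(frames, comments):
            fh.write(f"{mol.n_atoms}\n{comment}\n")
            for el, (x, y, z) in zip(mol.elements, mol.coords):
                fh.write(f"{el:<2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def _read_pdb(path: str) -> Molecule:
    elements: list[str] = []
    coords: list[list[float]] = []
    serial_to_index: dict[int, int] = {}
    conect: set[tuple[int, int]] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                try:
                    serial = int(line[6:11])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError:
                    raise ParseError(f"{path}:{ln}: malformed ATOM/HETATM record")
                el = line[76:78].strip().capitalize()
                if not el:
                    # fall back on the first alphabetic char of the atom name
                    name = line[12:16].strip()
                    el = next((c for c in name if c.isalpha()), "").capitalize()
                if el not in ELEMENTS:
                    raise ParseError(f"{path}:{ln}: unknown element {el!r}")
                serial_to_index[serial] = len(elements)
                elements.append(el)
                coords.append([x, y, z])
            elif rec == "CONECT":
                fields = line.split()[1:]
                try:
                    serials = [int(f) for f in fields]
                except ValueError:
                    raise ParseError(f"{path}:{ln}: malformed CONECT record")
                if serials:
                    a = serials[0]
                    for b in serials[1:]:
                        conect.add((min(a, b), max(a, b)))
    if not elements:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    coords_arr = np.array(coords)
    if conect:
        try:
            bonds = [
                (serial_to_index[a], serial_to_index[b], 1.0) for a, b in conect
            ]
        except KeyError as exc:
            raise ParseError(f"{path}: CONECT references unknown serial {exc}")
    else:
        bonds = infer_bonds(elements, coords_arr)
    return Molecule(elements, coords_arr, bonds)


def _write_pdb(path: str, mol: Molecule) -> None:
    with open(path, "w") as fh:
        for i, (el, (x, y, z)) in enumerate(zip(mol.elements, mol.coords), 1):
            name = f"{el}{i}"[:4]
            fh.write(
                f"HETATM{i:5d} {name:<4s} LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
            )
        adjacency: dict[int, list[int]] = {}
        for a, b, _ in mol.bonds:
            adjacency.setdefault(a, []).append(b)
            adjacency.setdefault(b, []).append(a)
        for a in sorted(adjacency):
            partners = sorted(adjacency[a])
            for k in range(0, len(partners), 4):
                chunk = partners[k : k + 4]
                fh.write(
                    "CONECT"
                    + f"{a + 1:5d}"
                    + "".join(f"{b + 1:5d}" for b in chunk)
                    + "\n"
                )
        fh.write("END\n")


def read_structure(path: str, format: Optional[str] = None) -> Molecule:
    """Read a structure file (``xyz`` or ``pdb``) into a :class:`Molecule`.

    The format is taken from the extension when not given.  Multi-frame
    XYZ returns the first frame (use :func:`read_xyz_frames` for all).
    """
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt == "xyz":
        return read_xyz_frames(path)[0]
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


def write_structure(path: str, mol: Molecule, format: Optional[str] = None) -> None:
    """Write a :class:`Molecule` as XYZ or PDB (ATOM/HETATM + CONECT)."""
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt == "xyz":
        write_xyz_frames(path, [mol])
    elif fmt == "pdb":
        _write_pdb(path, mol)
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")
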
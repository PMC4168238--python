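"""Unit conventions and conversions.

Internal conventions used throughout the package:

* coordinates        — Å
* energy             — Hartree
* gradients / forces — Hartree/Bohr (the atomic unit of force)

All conversion factors live in this module; nothing else in the package
hard-codes a unit factor.
"""

from __future__ import annotations

#: Bohr radius in Å (CODATA 2018).
BOHR_TO_ANGSTROM: float = 0.529177210903
ANGSTROM_TO_BOHR: float = 1.0 / BOHR_TO_ANGSTROM

#: One atomic unit of force (Hartree/Bohr) in nanonewtons, CODATA-derived:
#: E_h / a0 = 4.3597447e-18 J / 5.29177211e-11 m = 8.2387e-8 N.
AU_FORCE_TO_NN: float = 82.387

#: Hartree in Joule and other factors used by the vibrational analysis.
HARTREE_TO_JOULE: float = 4.3597447222071e-18
AMU_TO_KG: float = 1.66053906660e-27
SPEED_OF_LIGHT_CM_S: float = 2.99792458e10

_FORCE_UNITS = ("au", "nN")


def convert_force(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a force magnitude between atomic units (Hartree/Bohr) and nN.

    Parameters
    ----------
    value
        Non-negative force magnitude.
    from_unit, to_unit
        Either ``"au"`` or ``"nN"``.

    Returns
    -------
    float
        The converted magnitude.  Full precision is kept; round for
        display (e.g. ``0.07 au`` prints as ``5.77 nN`` at two decimals).
    """
    if from_unit not in _FORCE_UNITS or to_unit not in _FORCE_UNITS:
        raise ValueError(
            f"unknown force unit in ({from_unit!r}, {to_unit!r}); "
            f"expected one of {_FORCE_UNITS}"
        )
    if value < 0:
        raise ValueError(f"force must be non-negative, got {value}")
    if from_unit == to_unit:
        return float(value)
    if from_unit == "au":
        return float(value) * AU_FORCE_TO_NN
    return float(value) / AU_FORCE_TO_NN
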
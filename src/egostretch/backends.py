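"""Energy/gradient provider contract and diagnostics.

The pulling engine is backend-agnostic: anything exposing
``evaluate(coords_in_Å) -> (energy_in_Hartree, gradient_in_Hartree/Bohr)``
can drive it.  The built-in desk-scale backend is the toy molecular
mechanics model in :mod:`egostretch.toyff`; an external quantum-chemistry
code can be plugged in behind the same contract.  Backends must be
stateless per call — two calls with the same coordinates return the same
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .units import BOHR_TO_ANGSTROM

__all__ = ["EnergyModel", "GradientCheckReport", "check_gradient_fd", "SpringModel"]


@runtime_checkable
class EnergyModel(Protocol):
    """Contract: energy (Hartree) and per-atom gradient (Hartree/Bohr)."""

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        ...


@dataclass
class GradientCheckReport:
    """Outcome of a finite-difference gradient check."""

    max_deviation: float  # Hartree/Bohr
    worst_component: tuple[int, int]  # (atom, axis)
    passed: bool
    step: float
    tol: float


def check_gradient_fd(
    model: EnergyModel,
    coords: np.ndarray,
    step: float = 1e-4,
    tol: float = 1e-6,
) -> GradientCheckReport:
    """Compare the analytic gradient with central finite differences.

    ``step`` is the displacement in Å; deviations are reported in
    Hartree/Bohr so they are directly comparable to the gradient itself.
    """
    if step <= 0:
        raise ValueError("finite-difference step must be > 0")
    coords = np.asarray(coords, dtype=float)
    e0, grad = model.evaluate(coords)
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at the probe geometry")
    worst = (0, 0)
    max_dev = 0.0
    for i in range(coords.shape[0]):
        for ax in range(3):
            probe = coords.copy()
            probe[i, ax] += step
            ep, _ = model.evaluate(probe)
            probe[i, ax] -= 2 * step
            em, _ = model.evaluate(probe)
            if not (np.isfinite(ep) and np.isfinite(em)):
                raise ValueError(
                    f"non-finite energy while probing atom {i} axis {ax}"
                )
            # dE/dx in Hartree/Å, converted to Hartree/Bohr
            numeric = (ep - em) / (2 * step) * BOHR_TO_ANGSTROM
            dev = abs(numeric - grad[i, ax])
            if dev > max_dev:
                max_dev, worst = dev, (i, ax)
    return GradientCheckReport(
        max_deviation=float(max_dev),
        worst_component=worst,
        passed=bool(max_dev < tol),
        step=step,
        tol=tol,
    )


class SpringModel:
    """Pairwise harmonic springs — the analytically solvable test backend.

    ``springs`` is a list of ``(i, j, k, r0)`` with k in Hartree/Å² and
    r0 in Å: ``E = Σ ½ k (|ri − rj| − r0)²``.
    """

    def __init__(self, springs):
        self.springs = [(int(i), int(j), float(k), float(r0)) for i, j, k, r0 in springs]

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = np.asarray(coords, dtype=float)
        energy = 0.0
        grad = np.zeros_like(coords)  # Hartree/Å until the final conversion
        for i, j, k, r0 in self.springs:
            dvec = coords[i] - coords[j]
            d = float(np.linalg.norm(dvec))
            energy += 0.5 * k * (d - r0) ** 2
            if d > 1e-12:
                g = k * (d - r0) * dvec / d
                grad[i] += g
                grad[j] -= g
        return energy, grad * BOHR_TO_ANGSTROM
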
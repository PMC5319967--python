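"""Passive myocardial constitutive law.

Transversely isotropic exponential (Fung-type) strain energy in the local
fiber frame ``(f, c, r)`` — fiber, cross-fiber-in-wall, radial:

    W = C/2 (exp(Q) - 1)
    Q = b_f E_ff^2 + b_t (E_cc^2 + E_rr^2 + E_cr^2 + E_rc^2)
        + b_fs (E_fc^2 + E_cf^2 + E_fr^2 + E_rf^2)

with ``E`` the Green-Lagrange strain.  The myocardium is treated as
incompressible; the hydrostatic contribution ``-p J C^{-1}`` is handled by
the solver (per-element Lagrange multipliers with a volumetric augmentation)
and, for the standalone stress evaluation below, passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = ["PassiveMaterial", "strain_energy", "second_pk_stress", "NonphysicalStrainError"]

_Q_OVERFLOW = 200.0


class NonphysicalStrainError(FloatingPointError):
    """Exponent Q exceeded the overflow guard — the strain state is nonphysical."""


@dataclass(frozen=True)
class PassiveMaterial:
    """Stiffness scale and exponents of the passive strain energy.

    The default exponent ratios are the widely used adult-literature values;
    the stress scale ``C`` is calibrated against fetal end-diastolic data
    (see ``fetallv.mechanics.calibrate_passive_stiffness``).
    """

    C: float = 0.6  # kPa, stress scale (calibrated)
    b_f: float = 18.48  # fiber exponent
    b_t: float = 3.58  # transverse exponent
    b_fs: float = 1.627  # fiber-transverse shear exponent
    incompressibility: Literal["lagrange_multiplier", "penalty"] = "lagrange_multiplier"
    kappa: float = 250.0  # kPa, volumetric augmentation / penalty modulus

    def __post_init__(self):
        if min(self.C, self.b_f, self.b_t, self.b_fs) <= 0:
            raise ValueError("C and all exponent coefficients must be positive")

    def with_scale(self, C: float) -> "PassiveMaterial":
        return replace(self, C=C)

    @property
    def exponent_matrix(self) -> np.ndarray:
        """Symmetric coefficient matrix B with Q = sum_ab B_ab E_ab^2."""
        bf, bt, bfs = self.b_f, self.b_t, self.b_fs
        return np.array([[bf, bfs, bfs], [bfs, bt, bt], [bfs, bt, bt]])


def _exponent(E: np.ndarray, mat: PassiveMaterial) -> np.ndarray:
    Q = np.einsum("ab,...ab->...", mat.exponent_matrix, E * E)
    if np.any(Q > _Q_OVERFLOW):
        raise NonphysicalStrainError(
            f"strain-energy exponent exceeded {_Q_OVERFLOW}; strains are nonphysical"
        )
    return Q


def strain_energy(E: np.ndarray, mat: PassiveMaterial) -> np.ndarray:
    """Strain-energy density (kPa) from fiber-frame Green strain ``E``.

    ``E`` may be a single 3x3 symmetric tensor or a batch ``(..., 3, 3)``.
    """
    E = np.asarray(E, dtype=float)
    if not np.allclose(E, np.swapaxes(E, -1, -2), atol=1e-10):
        raise ValueError("Green strain must be symmetric")
    return 0.5 * mat.C * np.expm1(_exponent(E, mat))


def second_pk_stress(
    E: np.ndarray, mat: PassiveMaterial, hydrostatic_pressure: float | np.ndarray = 0.0
) -> np.ndarray:
    """Second Piola-Kirchhoff stress (kPa) in the fiber frame.

    The passive part is the exact derivative dW/dE; the incompressibility
    part is ``-p J C^{-1}`` with ``C = 2E + I`` the right Cauchy-Green tensor.
    """
    E = np.asarray(E, dtype=float)
    Q = _exponent(E, mat)
    S = mat.C * np.exp(Q)[..., None, None] * mat.exponent_matrix * E
    p = np.asarray(hydrostatic_pressure, dtype=float)
    if np.any(p != 0):
        Cg = 2.0 * E + np.eye(3)
        J = np.sqrt(np.linalg.det(Cg))
        S = S - p[..., None, None] * J[..., None, None] * np.linalg.inv(Cg)
    return S
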
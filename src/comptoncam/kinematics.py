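"""Closed-form Compton scattering kinematics.

These relations are shared by the event simulator and the cone-based
reconstructor.  For a photon of energy :math:`E_\\gamma` scattering off an
electron at rest, the scattered-photon energy as a function of the
scattering angle :math:`\\theta` is

.. math::

    E_\\gamma' = \\frac{E_\\gamma}{1 + (E_\\gamma/m_e c^2)(1 - \\cos\\theta)},

which is monotone decreasing on :math:`[0, \\pi]` and therefore invertible:
from the energy ``e1`` deposited on the recoil electron the scattering
angle is recovered through

.. math::

    \\cos\\theta = 1 - m_e c^2\\left(\\frac{1}{E_\\gamma - E_1}
                  - \\frac{1}{E_\\gamma}\\right).

Propagating an energy uncertainty ``de1`` through this inverse gives the
cone half-angle uncertainty

.. math::

    d\\theta = \\frac{m_e c^2 \\, dE_1}{\\sin\\theta\\,(E_\\gamma - E_1)^2},

which shrinks with increasing photon energy — the reason Compton imaging
resolution improves for harder gammas.

All energies are in MeV, all angles in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicsConstants",
    "CONSTANTS",
    "KinematicallyForbiddenError",
    "scattered_energy",
    "scattering_angle",
    "angular_uncertainty",
]


@dataclass(frozen=True)
class PhysicsConstants:
    """Fixed physical constants of the boron-capture imaging problem.

    Attributes
    ----------
    electron_rest_energy : float
        Electron rest energy ``m_e c^2`` in MeV.
    source_photon_energy : float
        Energy of the prompt de-excitation gamma of ⁷Li* in MeV.  This is
        the imaging signal of the ¹⁰B(n,α)⁷Li reaction.
    reaction_q_value : float
        Q value of the ¹⁰B(n,α)⁷Li capture reaction in MeV.  In the
        dominant (~94%) branch the 0.478 MeV photon carries away part of
        it, leaving ``reaction_q_value - source_photon_energy`` = 2.31 MeV
        of combined kinetic energy on the alpha and the recoiling ⁷Li.
    """

    electron_rest_energy: float = 0.511
    source_photon_energy: float = 0.478
    reaction_q_value: float = 2.79

    def __post_init__(self) -> None:
        if not (
            self.electron_rest_energy > 0
            and self.source_photon_energy > 0
            and self.reaction_q_value > 0
        ):
            raise ValueError("physics constants must be strictly positive")
        if not self.source_photon_energy < self.reaction_q_value:
            raise ValueError("photon energy must be below the reaction Q value")

    @property
    def branch_kinetic_energy(self) -> float:
        """Kinetic energy left to the alpha + ⁷Li pair in the photon branch."""
        return self.reaction_q_value - self.source_photon_energy


#: Module-wide constants; the electron rest energy is deliberately not a
#: configuration knob.
CONSTANTS = PhysicsConstants()


class KinematicallyForbiddenError(ValueError):
    """Raised when measured energies imply ``cos(theta)`` outside [-1, 1].

    Such events are unphysical under the single-Compton-then-photoabsorption
    hypothesis and must be rejected (and counted) by callers rather than
    silently mapped to a sentinel angle.
    """


def scattered_energy(e_gamma, theta):
    """Scattered-photon energy after Compton scattering by angle ``theta``.

    Parameters
    ----------
    e_gamma : float or ndarray
        Incident photon energy in MeV, strictly positive.
    theta : float or ndarray
        Scattering angle in radians, in ``[0, pi]``.

    Returns
    -------
    float or ndarray
        ``E_gamma'`` in MeV, satisfying ``0 < E_gamma' <= e_gamma``.
    """
    e_gamma = np.asarray(e_gamma, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(e_gamma <= 0):
        raise ValueError("photon energy must be positive")
    if np.any((theta < 0) | (theta > np.pi)):
        raise ValueError("scattering angle must lie in [0, pi]")
    out = e_gamma / (
        1.0 + (e_gamma / CONSTANTS.electron_rest_energy) * (1.0 - np.cos(theta))
    )
    return out if out.ndim else float(out)


def scattering_angle(e_gamma, e1):
    """Compton scattering angle from the first-detector energy deposit.

    Inverts the scattered-energy relation: given the incident energy
    ``e_gamma`` and the recoil-electron deposit ``e1``, returns ``theta``
    such that ``scattered_energy(e_gamma, theta) == e_gamma - e1``.

    Raises
    ------
    KinematicallyForbiddenError
        If the implied ``cos(theta)`` falls outside ``[-1, 1]`` — the
        event cannot be a single Compton scatter and should be rejected.
    """
    e_gamma = np.asarray(e_gamma, dtype=float)
    e1 = np.asarray(e1, dtype=float)
    if np.any(e1 <= 0) or np.any(e1 >= e_gamma):
        raise ValueError("need 0 < e1 < e_gamma")
    cos_theta = 1.0 - CONSTANTS.electron_rest_energy * (
        1.0 / (e_gamma - e1) - 1.0 / e_gamma
    )
    # tiny float excursions past +/-1 at the endpoints are legitimate
    tol = 1e-12
    if np.any(cos_theta < -1.0 - tol) or np.any(cos_theta > 1.0 + tol):
        raise KinematicallyForbiddenError(
            "deposited energy implies cos(theta) outside [-1, 1]"
        )
    out = np.arccos(np.clip(cos_theta, -1.0, 1.0))
    return out if out.ndim else float(out)


def scattering_angle_or_nan(e_gamma, e1):
    """Vectorized variant of :func:`scattering_angle`.

    Kinematically forbidden entries come back as NaN instead of raising,
    so bulk event streams can be filtered with a mask while the caller
    counts the rejections.
    """
    e_gamma = np.asarray(e_gamma, dtype=float)
    e1 = np.asarray(e1, dtype=float)
    cos_theta = 1.0 - CONSTANTS.electron_rest_energy * (
        1.0 / (e_gamma - e1) - 1.0 / e_gamma
    )
    bad = (e1 <= 0) | (e1 >= e_gamma) | (cos_theta < -1.0) | (cos_theta > 1.0)
    theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
    return np.where(bad, np.nan, theta)


def angular_uncertainty(e_gamma, e1, de1):
    """Cone half-angle error propagated from the energy error ``de1``.

    ``d(theta) = m_e c^2 * dE1 / (sin(theta) * (E_gamma - E1)^2)``,
    i.e. the first-order propagation of ``de1`` through the inverse
    kinematics.  Linear in ``de1``; decreases with photon energy at fixed
    ``E1/E_gamma`` and ``theta``.

    Raises
    ------
    ValueError
        If the implied scattering angle is 0 or pi (``sin(theta)=0``, the
        propagation is singular there).
    """
    if np.any(np.asarray(de1) <= 0):
        raise ValueError("energy uncertainty must be positive")
    theta = scattering_angle(e_gamma, e1)
    sin_theta = np.sin(theta)
    if np.any(np.isclose(sin_theta, 0.0, atol=1e-12)):
        raise ValueError("singular geometry: theta at 0 or pi")
    e_gamma = np.asarray(e_gamma, dtype=float)
    e1 = np.asarray(e1, dtype=float)
    out = (
        CONSTANTS.electron_rest_energy
        * np.asarray(de1, dtype=float)
        / (sin_theta * (e_gamma - e1) ** 2)
    )
    return out if np.ndim(out) else float(out)
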
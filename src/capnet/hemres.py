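"""Closed-form two-phase hydraulic resistance of a single capillary.

A capillary of radius ``rc`` carries red blood cells (RBCs) in single
file.  The RBC column is modelled as a very viscous fluid core of radius
``r0 = 0.3 um + 0.8 rc`` surrounded by a plasma sleeve; gaps between
successive cells are plasma-filled.  Writing ``H`` for the axial fraction
of the vessel occupied by RBC segments (the tube-hematocrit convention of
single-file models), the vessel behaves as RBC-filled and plasma-only
segments in series, which yields the effective specific resistance

    r_e(H) = rho(H) + (rho_hat(H) - rho(H)) * H,

where ``rho`` is the Poiseuille plasma-only specific resistance and
``rho_hat`` the two-viscosity specific resistance of an RBC-filled
segment.  The plasma viscosity is inflated with hematocrit,
``mu1(H) = 1e-3 (16 + 5 H)/15`` Pa*s, a calibration against axisymmetric
Stokes finite-element simulations of explicit RBC trains.

All quantities are SI: radii and lengths in metres, viscosities in Pa*s,
resistances in Pa*s/m^3 and specific (per-unit-length) resistances in
Pa*s/m^4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

from .errors import DegenerateGeometry, OutOfDomain

__all__ = [
    "CapillaryGeometry",
    "ViscosityModel",
    "HematocritState",
    "ResistancePair",
    "rbc_core_radius",
    "velocity_profile",
    "flux",
    "capillary_resistance_full_rbc",
    "poiseuille_resistance",
    "specific_resistances",
    "effective_specific_resistance",
    "effective_resistance",
    "exact_tube_hematocrit",
    "plasma_viscosity",
]

#: plasma-sleeve intercept of the RBC-core radius law (m)
_R0_OFFSET = 0.3e-6
#: slope of the RBC-core radius law (dimensionless)
_R0_SLOPE = 0.8
#: radius at and below which the core law gives r0 >= rc (m)
RC_DEGENERATE = _R0_OFFSET / (1.0 - _R0_SLOPE)

ArrayLike = Union[float, np.ndarray]


def rbc_core_radius(rc: ArrayLike) -> ArrayLike:
    """Radius of the single-file RBC core, ``r0 = 0.3 um + 0.8 rc``.

    Parameters
    ----------
    rc : float or ndarray
        Capillary radius in metres; must exceed 1.5 um, the fixed point
        of the law where the plasma sleeve vanishes.

    Raises
    ------
    DegenerateGeometry
        If any ``rc <= 1.5 um`` (then ``r0 >= rc``).
    """
    rc = np.asarray(rc, dtype=float)
    if np.any(rc <= 0):
        raise DegenerateGeometry("capillary radius must be positive")
    if np.any(rc <= RC_DEGENERATE + 1e-30):
        raise DegenerateGeometry(
            f"rc <= {RC_DEGENERATE * 1e6:.2f} um gives an RBC core radius "
            "r0 >= rc; the two-phase model degenerates"
        )
    r0 = _R0_OFFSET + _R0_SLOPE * rc
    return float(r0) if r0.ndim == 0 else r0


def plasma_viscosity(H: ArrayLike) -> ArrayLike:
    """Calibrated hematocrit-dependent plasma viscosity, Pa*s.

    ``mu1(H) = 1e-3 (16 + 5 H)/15``; equals 0.0011 at H=0.1 and 0.0012
    at H=0.4, the two anchor points of the finite-element calibration.
    """
    H = np.asarray(H, dtype=float)
    mu = 1e-3 * (16.0 + 5.0 * H) / 15.0
    return float(mu) if mu.ndim == 0 else mu


@dataclass(frozen=True)
class CapillaryGeometry:
    """Radius, length and derived RBC-core radius of one vessel (m)."""

    rc: float
    L: float
    r0: float = field(init=False)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("capillary length must be positive")
        object.__setattr__(self, "r0", rbc_core_radius(self.rc))


def _constant_law(mu: float) -> Callable[[ArrayLike], ArrayLike]:
    def law(H: ArrayLike) -> ArrayLike:
        H = np.asarray(H, dtype=float)
        out = np.full_like(H, mu)
        return float(out) if out.ndim == 0 else out

    return law


@dataclass(frozen=True)
class ViscosityModel:
    """Plasma and RBC-substance viscosities (Pa*s).

    ``mu1_law`` maps tube hematocrit to plasma viscosity.  The default is
    the calibrated law ``1e-3 (16 + 5H)/15``; use :meth:`constant` to pin
    the plasma viscosity at a fixed value (e.g. 0.001 Pa*s, the raw
    plasma value used by the finite-element reference model).

    ``mu2`` is large (default 0.1 Pa*s) so that the RBC core is
    effectively rigid; increasing it further has almost no effect.
    """

    mu1_base: float = 1e-3
    mu2: float = 0.1
    mu1_law: Callable[[ArrayLike], ArrayLike] = plasma_viscosity

    def __post_init__(self) -> None:
        if not (self.mu2 > self.mu1_base > 0):
            raise ValueError("require mu2 > mu1_base > 0")

    @classmethod
    def constant(cls, mu1: float = 1e-3, mu2: float = 0.1) -> "ViscosityModel":
        """Model with hematocrit-independent plasma viscosity."""
        return cls(mu1_base=mu1, mu2=mu2, mu1_law=_constant_law(mu1))

    def mu1(self, H: ArrayLike) -> ArrayLike:
        return self.mu1_law(H)


@dataclass(frozen=True)
class HematocritState:
    """Tube hematocrit in the axial (L_hat/L) convention and the exact
    RBC volume fraction ``H (r0/rc)^2`` accounting for the plasma sleeve."""

    H: float
    H_exact: float

    @classmethod
    def from_radius(cls, H: float, rc: float) -> "HematocritState":
        return cls(H=H, H_exact=exact_tube_hematocrit(H, rc))


@dataclass(frozen=True)
class ResistancePair:
    """Specific resistances (Pa*s/m^4) of plasma-only and RBC-filled
    capillary segments."""

    rho: ArrayLike
    rho_hat: ArrayLike

    @property
    def beta(self) -> ArrayLike:
        """Relative extra resistance of an RBC-filled segment."""
        return self.rho_hat / self.rho - 1.0


def _check_H(H: ArrayLike) -> np.ndarray:
    H = np.asarray(H, dtype=float)
    if np.any((H < 0) | (H > 1)):
        raise ValueError("tube hematocrit must lie in [0, 1]")
    return H


def velocity_profile(
    r: ArrayLike,
    geom: CapillaryGeometry,
    dp: float,
    visc: ViscosityModel | None = None,
) -> ArrayLike:
    """Axial velocity (m/s) of the fully RBC-filled two-viscosity flow.

    Piecewise-parabolic: a blunt profile inside the viscous RBC core
    (r < r0) matched continuously to the plasma-sleeve parabola, with
    no slip at the wall.  ``dp`` is the pressure drop over the vessel
    length; the returned value is the speed along the pressure gradient.
    """
    if visc is None:
        visc = ViscosityModel.constant()
    if dp <= 0:
        raise ValueError("pressure drop must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > geom.rc * (1 + 1e-12)):
        raise OutOfDomain("radial coordinate outside [0, rc]")
    A = dp / geom.L
    mu1 = visc.mu1_base
    rc2, r02 = geom.rc**2, geom.r0**2
    sleeve = A * (rc2 - r**2) / (4.0 * mu1)
    core = A * (rc2 - r02) / (4.0 * mu1) + A * (r02 - r**2) / (4.0 * visc.mu2)
    v = np.where(r >= geom.r0, sleeve, core)
    return float(v) if v.ndim == 0 else v


def flux(geom: CapillaryGeometry, dp: float, visc: ViscosityModel | None = None) -> float:
    """Volumetric flux (m^3/s) of the fully RBC-filled flow at pressure
    drop ``dp``: ``q = (pi dp / 8 L) [(rc^4 - r0^4)/mu1 + r0^4/mu2]``."""
    if visc is None:
        visc = ViscosityModel.constant()
    return dp / capillary_resistance_full_rbc(geom, visc)


def capillary_resistance_full_rbc(
    geom: CapillaryGeometry, visc: ViscosityModel | None = None
) -> float:
    """Hydraulic resistance (Pa*s/m^3) of a capillary whose entire length
    carries the RBC core: ``(8L/pi) [(rc^4-r0^4)/mu1 + r0^4/mu2]^-1``.

    Collapses to Poiseuille when ``mu2 == mu1`` and to the rigid-core
    annulus limit as ``mu2 -> inf``.
    """
    if visc is None:
        visc = ViscosityModel.constant()
    rc4 = geom.rc**4
    r04 = geom.r0**4
    denom = (rc4 - r04) / visc.mu1_base + r04 / visc.mu2
    return (8.0 * geom.L / np.pi) / denom


def poiseuille_resistance(rc: ArrayLike, L: ArrayLike, mu1: float) -> ArrayLike:
    """Poiseuille resistance ``8 L mu1 / (pi rc^4)`` in Pa*s/m^3."""
    rc = np.asarray(rc, dtype=float)
    if np.any(rc <= 0) or np.any(np.asarray(L) <= 0) or mu1 <= 0:
        raise ValueError("rc, L and mu1 must be positive")
    R = 8.0 * np.asarray(L, dtype=float) * mu1 / (np.pi * rc**4)
    return float(R) if R.ndim == 0 else R


def specific_resistances(
    rc: ArrayLike, H: ArrayLike, visc: ViscosityModel | None = None
) -> ResistancePair:
    """Per-unit-length resistances (Pa*s/m^4) of plasma-only and
    RBC-filled segments, evaluated at plasma viscosity ``mu1(H)``:

        rho_hat = (8/pi) [(rc^4 - r0^4)/mu1 + r0^4/mu2]^-1
        rho     = (8/pi) [rc^4/mu1]^-1
    """
    if visc is None:
        visc = ViscosityModel()
    H = _check_H(H)
    rc = np.asarray(rc, dtype=float)
    r0 = np.asarray(rbc_core_radius(rc))
    mu1 = np.asarray(visc.mu1(H), dtype=float)
    rc4, r04 = rc**4, r0**4
    rho = 8.0 * mu1 / (np.pi * rc4)
    rho_hat = (8.0 / np.pi) / ((rc4 - r04) / mu1 + r04 / visc.mu2)
    if rho.ndim == 0 and rho_hat.ndim == 0:
        return ResistancePair(rho=float(rho), rho_hat=float(rho_hat))
    return ResistancePair(rho=rho, rho_hat=rho_hat)


def effective_specific_resistance(
    rc: ArrayLike, H: ArrayLike, visc: ViscosityModel | None = None
) -> ArrayLike:
    """Hematocrit-dependent effective specific resistance (Pa*s/m^4),

        r_e(H) = rho(H) + (rho_hat(H) - rho(H)) * H,

    the series combination of RBC-filled and plasma segments weighted by
    the axial occupancy ``H``.  Strictly increasing in ``H`` under the
    default calibrated viscosity law.
    """
    pair = specific_resistances(rc, H, visc)
    H = np.asarray(H, dtype=float)
    re = pair.rho + (pair.rho_hat - pair.rho) * H
    return float(re) if np.ndim(re) == 0 else re


def effective_resistance(
    geom: CapillaryGeometry, H: float, visc: ViscosityModel | None = None
) -> float:
    """Effective resistance (Pa*s/m^3) of one capillary, ``r_e(H) * L``.

    Algebraically identical to the serial form
    ``L_hat * rho_hat + (L - L_hat) * rho`` with ``L_hat = H L``, and to
    ``R (1 + H beta)`` with ``beta = rho_hat/rho - 1``.
    """
    return effective_specific_resistance(geom.rc, H, visc) * geom.L


def exact_tube_hematocrit(H: ArrayLike, rc: ArrayLike) -> ArrayLike:
    """RBC volume fraction ``H (r0/rc)^2`` accounting for the plasma
    sleeve; always below the axial-convention value ``H``."""
    H = _check_H(H)
    rc = np.asarray(rc, dtype=float)
    r0 = np.asarray(rbc_core_radius(rc))
    He = H * (r0 / rc) ** 2
    return float(He) if He.ndim == 0 else He
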
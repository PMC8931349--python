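"""Closed-form contact-force models and derived moduli.

The material is a Kelvin-Voigt element (spring ``E0``, dashpot ``eta``) in
parallel with a Maxwell element (spring ``E1``, dashpot ``lam*E1``, relaxation
time ``lam``).  Indented at constant speed ``v`` by a rigid sphere of radius
``R``, the approach force admits an explicit force-indentation relation

    F(delta) = F_el(E0, delta)
             + F_el(E1, delta) * exp(-alpha1 * delta / (v * lam))
             + alpha2 * delta**alpha3 * R**alpha4 * eta * v

where ``F_el`` is the large-deformation (hyperelastic) correction of the Hertz
sphere-on-half-space law and ``alpha1..alpha4`` are dimensionless constants
calibrated once against finite-element indentation simulations.

All quantities are strict SI (m, s, N, Pa, Pa.s).  Conversion to the nN / um /
kPa units habitual in force spectroscopy happens only at presentation level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ViscoelasticParams",
    "CalibrationConstants",
    "ProbeGeometry",
    "DerivedModuli",
    "hertz_force",
    "ding_force",
    "kvm_force",
    "kvm_force_terms",
    "derived_moduli",
    "stokes_drag",
    "maxwell_remaining_fraction",
]

_NU_TOL = 1e-9


@dataclass(frozen=True)
class ViscoelasticParams:
    """Kelvin-Voigt-Maxwell material state.

    Parameters
    ----------
    E0 : float
        Kelvin-Voigt (instantaneously and permanently load-bearing) Young's
        modulus [Pa].
    E1 : float
        Maxwell Young's modulus [Pa]; its contribution relaxes away with
        time constant ``lam``.
    lam : float
        Maxwell relaxation time [s].
    eta : float
        Apparent viscosity of the parallel dashpot [Pa s].
    nu : float
        Poisson ratio; 0.5 (incompressible) by default.
    """

    E0: float
    E1: float = 0.0
    lam: float = 0.0
    eta: float = 0.0
    nu: float = 0.5

    def __post_init__(self) -> None:
        if self.E0 < 0 or self.E1 < 0 or self.lam < 0 or self.eta < 0:
            raise ValueError("E0, E1, lam and eta must be non-negative")
        if not (0.0 <= self.nu <= 0.5 + _NU_TOL):
            raise ValueError(f"Poisson ratio {self.nu} outside [0, 0.5]")
        if self.E1 > 0 and self.lam == 0:
            raise ValueError("Maxwell arm undefined: E1 > 0 requires lam > 0")


@dataclass(frozen=True)
class CalibrationConstants:
    """Dimensionless constants of the explicit force-indentation relation.

    Calibrated once against finite-element simulations of spherical
    indentation of a KVM half-space; not refitted per curve.
    """

    alpha1: float = 0.365
    alpha2: float = 7.25
    alpha3: float = 0.5
    alpha4: float = 0.5

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.alpha3, self.alpha4) <= 0:
            raise ValueError("all calibration constants must be positive")


@dataclass
class ProbeGeometry:
    """Indenter and sample geometry.

    ``R`` is the bead radius.  For a rounded (mitotic-like) cell of radius
    ``Rcell`` the contact is sphere-on-sphere and an effective radius
    ``Reff = 1/(1/Rcell + 1/R)`` replaces ``R`` in the force models, with the
    confinement factor ``K = Rcell^(1/3)/(Rcell^(1/3)+Reff^(1/3))`` scaling
    the indentation.  ``h`` is the sample thickness used by the bottom-effect
    diagnostic.
    """

    R: float
    Rcell: float | None = None
    h: float | None = None

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("bead radius R must be positive")
        if self.Rcell is not None and self.Rcell <= 0:
            raise ValueError("cell radius Rcell must be positive")
        if self.h is not None and self.h <= 0:
            raise ValueError("sample thickness h must be positive")

    @property
    def Reff(self) -> float:
        """Effective contact radius; equals R for a flat sample."""
        if self.Rcell is None:
            return self.R
        return 1.0 / (1.0 / self.Rcell + 1.0 / self.R)

    @property
    def K(self) -> float | None:
        """Confinement correction factor, or None for a flat sample."""
        if self.Rcell is None:
            return None
        a, b = self.Rcell ** (1 / 3), self.Reff ** (1 / 3)
        return a / (a + b)


@dataclass(frozen=True)
class DerivedModuli:
    """Moduli robust to the lam/t_ind degeneracy of the four-parameter fit."""

    Eu: float      # unrelaxed modulus E0 + E1 [Pa]
    Eapp: float    # apparent modulus on the indentation timescale [Pa]
    t_ind: float   # indentation time delta_max / v [s]

    def __post_init__(self) -> None:
        if not (self.Eapp <= self.Eu + 1e-9 * max(self.Eu, 1.0)):
            raise ValueError("Eapp cannot exceed Eu")
        if self.t_ind <= 0:
            raise ValueError("t_ind must be positive")


def _check_delta(delta, clip: bool):
    delta = np.asarray(delta, dtype=float)
    if clip:
        return np.maximum(delta, 0.0)
    if np.any(delta < 0):
        raise ValueError("negative indentation; pass clip=True for piecewise contact")
    return delta


def hertz_force(E: float, nu: float, R: float, delta, *, clip: bool = False):
    """Hertz sphere-on-half-space force F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2).

    With ``clip=True`` negative indentations (pre-contact) return zero force,
    which is the convention the curve fitter uses across the baseline.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if not nu < 1:
        raise ValueError("nu must be < 1")
    d = _check_delta(delta, clip)
    out = (4.0 / 3.0) * E / (1.0 - nu**2) * math.sqrt(R) * d**1.5
    return out if isinstance(delta, np.ndarray) or np.ndim(delta) else float(out)


def ding_force(E: float, nu: float, R: float, delta, *, clip: bool = False):
    """Hertz force with the large-deformation correction (1 - 0.15 delta/R).

    The correction extends the sphere contact law to indentation depths
    comparable to the probe radius for a neo-Hookean half-space.
    """
    d = _check_delta(delta, clip)
    out = hertz_force(E, nu, R, d, clip=clip) * (1.0 - 0.15 * d / R)
    return out if isinstance(delta, np.ndarray) or np.ndim(delta) else float(out)


def kvm_force_terms(
    p: ViscoelasticParams,
    c: CalibrationConstants,
    R: float,
    v: float,
    delta,
    *,
    clip: bool = False,
):
    """The three addends of the explicit KVM relation.

    Returns ``(F_kv_spring, F_maxwell, F_viscous)``: the Kelvin-Voigt spring
    force, the exponentially relaxing Maxwell-arm force, and the dashpot drag
    on the wetted probe segment.  Kept separate for diagnostics.
    """
    if v <= 0:
        raise ValueError("indenter speed v must be positive")
    d = _check_delta(delta, clip)
    f0 = ding_force(p.E0, p.nu, R, d, clip=clip)
    if p.E1 > 0:
        # elapsed contact time is delta/v under the constant-velocity approach
        f1 = ding_force(p.E1, p.nu, R, d, clip=clip) * np.exp(
            -c.alpha1 * d / (v * p.lam)
        )
    else:
        f1 = np.zeros_like(d)
    f2 = c.alpha2 * d**c.alpha3 * R**c.alpha4 * p.eta * v
    return f0, f1, f2


def kvm_force(
    p: ViscoelasticParams,
    c: CalibrationConstants,
    R: float,
    v: float,
    delta,
    *,
    clip: bool = False,
):
    """Total approach force of the explicit KVM force-indentation relation."""
    f0, f1, f2 = kvm_force_terms(p, c, R, v, delta, clip=clip)
    out = f0 + f1 + f2
    return out if isinstance(delta, np.ndarray) or np.ndim(delta) else float(out)


def derived_moduli(
    p: ViscoelasticParams,
    c: CalibrationConstants,
    delta_max: float,
    v: float,
) -> DerivedModuli:
    """Unrelaxed and apparent moduli for an indentation to depth ``delta_max``.

    ``Eu = E0 + E1`` is the total elasticity before any Maxwell relaxation;
    ``Eapp = E0 + E1 exp(-alpha1 delta_max / (v lam))`` is the elasticity
    apparent on the timescale ``t_ind = delta_max / v`` of the measurement.
    Both are far less sensitive than (E0, E1, lam) individually when lam and
    t_ind are widely separated.
    """
    if delta_max <= 0 or v <= 0:
        raise ValueError("delta_max and v must be positive")
    Eu = p.E0 + p.E1
    if p.E1 > 0:
        Eapp = p.E0 + p.E1 * math.exp(-c.alpha1 * delta_max / (v * p.lam))
    else:
        Eapp = p.E0
    return DerivedModuli(Eu=Eu, Eapp=Eapp, t_ind=delta_max / v)


def stokes_drag(mu: float, R: float, v: float) -> float:
    """Stokes drag 6 pi mu R v on the spherical probe moving through the medium.

    Reported alongside fits as a negligibility diagnostic: for water and
    typical probe speeds it is four orders of magnitude below the measured
    material resistance.
    """
    if mu < 0 or R <= 0 or v < 0:
        raise ValueError("mu, v must be non-negative and R positive")
    return 6.0 * math.pi * mu * R * v


def maxwell_remaining_fraction(t_ind: float, lam: float) -> float:
    """Fraction exp(-t_ind/lam) of the Maxwell modulus still unrelaxed at t_ind.

    Rationale for the lam fitting box [t_ind/5, 10 t_ind]: at the upper bound
    ~0.9 of E1 is still present (nearly elastic, E0/E1 indistinguishable), at
    the lower bound only ~0.006 remains (fully relaxed, E1 arbitrary).
    """
    if t_ind <= 0 or lam <= 0:
        raise ValueError("t_ind and lam must be positive")
    return math.exp(-t_ind / lam)
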
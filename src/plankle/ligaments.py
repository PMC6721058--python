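"""Planar nonlinear cable mechanics for the ligaments.

Each ligament is a massless cable between a basis-side attachment ``a``
(TFS frame) and a moving-side attachment ``b_local`` (TCS frame).  The cable
carries tension only: the force is zero whenever the strain is non-positive.
Above slack length the tension follows an exponential force--strain law with
two material coefficients ``A`` (force scale, N) and ``B`` (dimensionless
strain sensitivity).

Two variants of the law are provided (see :data:`FORCE_MODELS`):

``exp_shifted``
    ``F = A * exp(B*eps - 1)``, the law exactly as commonly typeset.  It is
    discontinuous at activation: the tension jumps from 0 to ``A/e`` as the
    strain crosses zero.
``exp_minus_one``
    ``F = A * (exp(B*eps) - 1)``, the classical exponential ligament law,
    continuous at activation.

Both are conservative; closed-form elastic potentials are provided for the
energy-based diagnostics in :mod:`plankle.statics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateGeometryError
from .kinematics import JointState, as_vec2, to_basis_frame

__all__ = [
    "FORCE_MODELS",
    "Ligament2D",
    "LigamentLoad",
    "force_magnitude",
    "ligament_length",
    "ligament_strain",
    "ligament_force",
    "ligament_moment",
    "ligament_energy",
]

FORCE_MODELS = ("exp_shifted", "exp_minus_one")

# Overflow guard: caps the exponent so that absurd trial states visited by
# the solver return a huge-but-finite force instead of inf.
_MAX_EXPONENT = 500.0

_MIN_LENGTH = 1e-12  # mm; below this the cable direction is undefined


@dataclass(frozen=True)
class Ligament2D:
    """A planar ligament cable.

    Attributes
    ----------
    name : str
        Anatomical label (``ATT``, ``TC``, ``PTT``, ``ATF``, ``CF``, ``PTF``
        in the default fixture) or free text.
    a : (2,) ndarray
        Attachment on the basis (TFS frame), mm.
    b_local : (2,) ndarray
        Attachment on the moving body (TCS frame), mm.
    l_slack : float
        Slack length, mm; the cable is force-free at or below it.
    A, B : float
        Material coefficients of the exponential law: ``A`` in N (>= 0),
        ``B`` dimensionless (> 0).
    """

    name: str
    a: np.ndarray
    b_local: np.ndarray
    l_slack: float
    A: float
    B: float

    def __post_init__(self):
        object.__setattr__(self, "a", as_vec2(self.a, f"{self.name}.a"))
        object.__setattr__(self, "b_local", as_vec2(self.b_local, f"{self.name}.b_local"))
        if not (self.l_slack > 0):
            raise ValueError(f"{self.name}: l_slack must be > 0, got {self.l_slack}")
        if not (self.A >= 0):
            raise ValueError(f"{self.name}: A must be >= 0, got {self.A}")
        if not (self.B > 0):
            raise ValueError(f"{self.name}: B must be > 0, got {self.B}")


@dataclass(frozen=True)
class LigamentLoad:
    """Resolved load state of one ligament at one joint configuration.

    ``force_vector`` is the force the cable applies to the moving body
    (tension pulls the moving-side attachment toward the basis-side one);
    ``moment`` is its moment about the basis-frame origin, N*mm.
    """

    length: float
    strain: float
    force_value: float
    force_vector: np.ndarray
    moment: float
    active: bool


def force_magnitude(A: float, B: float, strain, force_model: str = "exp_shifted"):
    """Tension of an exponential cable at the given strain (vectorized).

    Returns 0 for any non-positive strain (cables cannot push).
    """
    if force_model not in FORCE_MODELS:
        raise ValueError(f"unknown force_model {force_model!r}; choose from {FORCE_MODELS}")
    eps = np.asarray(strain, dtype=float)
    if force_model == "exp_shifted":
        val = A * np.exp(np.minimum(B * eps - 1.0, _MAX_EXPONENT))
    else:  # exp_minus_one
        val = A * np.expm1(np.minimum(B * eps, _MAX_EXPONENT))
    out = np.where(eps > 0.0, val, 0.0)
    return float(out) if np.isscalar(strain) or out.ndim == 0 else out


def ligament_length(lig: Ligament2D, state: JointState) -> float:
    """Current cable length: distance between attachments in the basis frame."""
    b = to_basis_frame(lig.b_local, state)
    length = float(np.linalg.norm(b - lig.a))
    if length < _MIN_LENGTH:
        raise DegenerateGeometryError(
            f"{lig.name}: attachments coincide at this state; cable direction undefined"
        )
    return length


def ligament_strain(length: float, l_slack: float) -> float:
    """Engineering strain ``(l - l_slack) / l_slack``; zero at slack length."""
    if not (l_slack > 0):
        raise ValueError(f"l_slack must be > 0, got {l_slack}")
    return (length - l_slack) / l_slack


def ligament_moment(application_point, force_vector) -> float:
    """Planar cross product ``bx*Fy - by*Fx`` about the basis-frame origin."""
    b = as_vec2(application_point, "application_point")
    f = as_vec2(force_vector, "force_vector")
    return float(b[0] * f[1] - b[1] * f[0])


def ligament_force(
    lig: Ligament2D, state: JointState, force_model: str = "exp_shifted"
) -> LigamentLoad:
    """Resolve one ligament at one state: length, strain, force, moment."""
    b = to_basis_frame(lig.b_local, state)
    d = b - lig.a
    length = float(np.linalg.norm(d))
    if length < _MIN_LENGTH:
        raise DegenerateGeometryError(
            f"{lig.name}: attachments coincide at this state; cable direction undefined"
        )
    strain = ligament_strain(length, lig.l_slack)
    value = force_magnitude(lig.A, lig.B, strain, force_model)
    if strain > 0.0:
        vec = -(d / length) * value
        active = True
    else:
        vec = np.zeros(2)
        value = 0.0
        active = False
    return LigamentLoad(
        length=length,
        strain=strain,
        force_value=float(value),
        force_vector=vec,
        moment=ligament_moment(b, vec),
        active=active,
    )


def ligament_energy(
    lig: Ligament2D, state: JointState, force_model: str = "exp_shifted"
) -> float:
    """Elastic potential stored in the cable, N*mm.

    Closed-form integral of the force law over length, zero at and below
    slack length.  For ``exp_shifted`` the potential is continuous but has a
    slope jump at activation, mirroring the force discontinuity.
    """
    length = ligament_length(lig, state)
    eps = ligament_strain(length, lig.l_slack)
    if eps <= 0.0:
        return 0.0
    A, B, ls = lig.A, lig.B, lig.l_slack
    if force_model == "exp_shifted":
        e = np.exp(min(B * eps - 1.0, _MAX_EXPONENT))
        return float(A * ls / B * (e - np.exp(-1.0)))
    if force_model == "exp_minus_one":
        return float(A * ls * (np.expm1(min(B * eps, _MAX_EXPONENT)) / B - eps))
    raise ValueError(f"unknown force_model {force_model!r}; choose from {FORCE_MODELS}")
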
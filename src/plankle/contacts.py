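"""Hertzian sphere-sphere cartilage contact.

The tibiotalar cartilage is idealized as conforming (internal) sphere-sphere
contact: a concave female sphere of radius ``r_a`` fixed to the basis and a
convex male sphere of radius ``r_b < r_a`` fixed to the moving body.  The
surfaces interpenetrate when the center distance exceeds ``r_a - r_b``; the
normal force then follows the Hertz law ``F = K * delta**1.5`` with a
generalized stiffness ``K`` derived from the radii and the (shared) elastic
constants of the cartilage.

Because the two anatomical contact pairs sit symmetrically in the frontal
plane, they project onto the same sagittal location; a single
:class:`ContactPair` with ``multiplicity=2`` represents both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinematics import JointState, as_vec2, to_basis_frame
from .ligaments import ligament_moment as _cross  # same planar cross product

__all__ = [
    "ContactPair",
    "ContactLoad",
    "generalized_stiffness",
    "penetration",
    "contact_load",
    "contact_energy",
]

_MIN_DISTANCE = 1e-12  # mm


def generalized_stiffness(E: float, nu: float, r_a: float, r_b: float) -> float:
    """Generalized Hertz stiffness for internal sphere-sphere contact.

    ``K = 2E / (3(1 - nu^2)) * sqrt(r_a r_b / (r_a - r_b))`` in N/mm^1.5,
    with E in MPa (N/mm^2) and both radii positive, female strictly larger.
    K grows as the spheres become more conforming (``r_a -> r_b``).
    """
    if not (r_b > 0 and r_a > r_b):
        raise ValueError(
            f"radii must satisfy r_a > r_b > 0 (female strictly larger), "
            f"got r_a={r_a}, r_b={r_b}"
        )
    if not (0 <= nu < 0.5):
        raise ValueError(f"Poisson's ratio must be in [0, 0.5), got {nu}")
    if not (E > 0):
        raise ValueError(f"Young's modulus must be > 0, got {E}")
    return 2.0 * E / (3.0 * (1.0 - nu**2)) * math.sqrt(r_a * r_b / (r_a - r_b))


@dataclass(frozen=True)
class ContactPair:
    """A female/male sphere pair.

    ``O_a`` is the female center in the basis frame, ``O_b_local`` the male
    center in the moving frame (mm).  ``multiplicity`` counts how many
    identical frontal-plane-symmetric pairs this record stands for; all
    resolved loads are scaled by it.
    """

    O_a: np.ndarray
    O_b_local: np.ndarray
    r_a: float
    r_b: float
    E: float
    nu: float
    multiplicity: int = 1

    def __post_init__(self):
        object.__setattr__(self, "O_a", as_vec2(self.O_a, "O_a"))
        object.__setattr__(self, "O_b_local", as_vec2(self.O_b_local, "O_b_local"))
        if not (isinstance(self.multiplicity, (int, np.integer)) and self.multiplicity >= 1):
            raise ValueError(f"multiplicity must be a positive integer, got {self.multiplicity}")
        # validates radii and elastic constants as a side effect
        object.__setattr__(
            self, "_K", generalized_stiffness(self.E, self.nu, self.r_a, self.r_b)
        )

    @property
    def K(self) -> float:
        """Generalized stiffness of a single pair, N/mm^1.5."""
        return self._K


@dataclass(frozen=True)
class ContactLoad:
    """Resolved load of a contact record (already scaled by multiplicity).

    ``force_vector`` pushes the male center back toward the female center;
    ``moment`` is about the basis-frame origin, N*mm.
    """

    penetration: float
    force_value: float
    force_vector: np.ndarray
    application_point: np.ndarray
    moment: float
    active: bool


def penetration(pair: ContactPair, state: JointState) -> float:
    """Relative penetration ``|O_b - O_a| + r_b - r_a`` (mm).

    Positive exactly when the male surface passes beyond the female surface;
    concentric spheres give ``r_b - r_a < 0`` (inactive).
    """
    O_b = to_basis_frame(pair.O_b_local, state)
    return float(np.linalg.norm(O_b - pair.O_a)) + pair.r_b - pair.r_a


def contact_load(pair: ContactPair, state: JointState) -> ContactLoad:
    """Resolve one contact record at one state.

    Force value ``K * delta**1.5`` per pair, direction along the center line
    pulling the male center back toward the female center; application point
    at ``O_b + n*(r_b + delta/2)``, i.e. half the penetration beyond the male
    surface along the outward normal ``n``.  Force and moment are scaled by
    ``multiplicity``.
    """
    O_b = to_basis_frame(pair.O_b_local, state)
    dvec = O_b - pair.O_a
    dist = float(np.linalg.norm(dvec))
    delta = dist + pair.r_b - pair.r_a
    if delta <= 0.0 or dist < _MIN_DISTANCE:
        return ContactLoad(
            penetration=delta,
            force_value=0.0,
            force_vector=np.zeros(2),
            application_point=O_b.copy(),
            moment=0.0,
            active=False,
        )
    n = dvec / dist
    value = pair.K * delta**1.5 * pair.multiplicity
    vec = -n * value
    b_c = O_b + n * (pair.r_b + delta / 2.0)
    return ContactLoad(
        penetration=delta,
        force_value=float(value),
        force_vector=vec,
        application_point=b_c,
        moment=_cross(b_c, vec),
        active=True,
    )


def contact_energy(pair: ContactPair, state: JointState) -> float:
    """Elastic potential of the Hertz contact, ``(2/5) K delta^{5/2}`` per
    pair (N*mm), scaled by multiplicity; zero without penetration."""
    delta = penetration(pair, state)
    if delta <= 0.0:
        return 0.0
    return 0.4 * pair.K * delta**2.5 * pair.multiplicity
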
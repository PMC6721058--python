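"""Deterministic synthetic joint geometry.

The anatomical geometry behind the published ankle results comes from
medical atlases and is available only as figures, so this module generates
a deterministic stand-in with the same topology: six named ligaments (ATT,
TC, PTT, ATF, CF, PTF) spanning the joint anterior-to-posterior and one
frontal-plane-symmetric Hertzian contact record of multiplicity 2.

Frame conventions of the default fixture
----------------------------------------
* basis-frame origin at the female (tibial plafond) sphere center;
* moving-frame origin at the male (talar dome) sphere center at neutral;
* anterior is -x (a right ankle viewed from the medial side), so a positive
  external moment -- plantarflexion by convention -- drives theta positive;
* at neutral the male center sits ``r_a - r_b`` above the female center
  (conforming internal contact), every ligament is exactly at slack length
  and the contact penetration is exactly zero (or ``contact_preload`` if
  requested), making the unloaded neutral pose an equilibrium.

The coefficients are chosen so the fixture reproduces the physiology the
planar model is meant to show: plantarflexion range larger than
dorsiflexion, a pronounced ramp-up of angular stiffness, near-isometric TC
and CF, and peak ligament/contact forces of a few hundred newtons at 5 N*m.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from .contacts import ContactPair
from .finetune import Ligament3D
from .kinematics import JointState
from .ligaments import Ligament2D
from .statics import JointModel, SolverSettings

__all__ = [
    "LIGAMENT_NAMES",
    "FixtureSpec",
    "default_ankle_fixture",
    "synthetic_ligament3d",
    "perturb_attachment",
]

LIGAMENT_NAMES = ("ATT", "TC", "PTT", "ATF", "CF", "PTF")

# name -> (a, b_neutral, A, B): attachments in basis-frame mm at the neutral
# pose (anterior = -x, proximal = +y), force scale A in N, strain
# sensitivity B dimensionless.  TC and CF run almost through the joint
# center (near-isometric); ATT/PTT carry the large sagittal moment arms;
# ATF/PTF are short and nearly horizontal with small arms.
_DEFAULT_TABLE = {
    "ATT": ((-8.0, 18.0), (-22.0, -8.0), 1.2, 33.0),
    "TC": ((-1.0, 20.0), (1.0, -22.0), 0.5, 30.0),
    "PTT": ((6.0, 16.0), (20.0, -10.0), 2.2, 55.0),
    "ATF": ((5.0, 4.0), (-14.0, 0.0), 0.5, 22.0),
    "CF": ((4.0, 14.0), (-6.5, -20.0), 0.5, 28.0),
    "PTF": ((4.0, 3.0), (18.0, -2.0), 0.5, 22.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the generated geometry.

    ``scale`` multiplies every coordinate and radius; ``E`` (MPa) and ``nu``
    are the cartilage constants; ``contact_preload`` (mm) optionally starts
    the contact mildly penetrated at neutral, covering the reading in which
    the joint is compressed at rest (the default keeps the unloaded neutral
    an exact equilibrium).
    """

    scale: float = 1.0
    E: float = 10.0
    nu: float = 0.46
    r_a: float = 22.0
    r_b: float = 20.0
    contact_preload: float = 0.0
    force_model: str = "exp_shifted"

    def __post_init__(self):
        if not (self.scale > 0):
            raise ValueError("scale must be > 0")
        if self.contact_preload < 0:
            raise ValueError("contact_preload must be >= 0")


def default_ankle_fixture(spec: FixtureSpec | None = None) -> JointModel:
    """Build the default six-ligament, two-contact planar ankle model.

    Deterministic: identical output on every call.  Slack lengths are
    computed at the neutral state, so with zero preload the neutral pose is
    an exact unloaded equilibrium.
    """
    spec = spec if spec is not None else FixtureSpec()
    s = spec.scale
    p0 = np.array([0.0, (spec.r_a - spec.r_b) * s + spec.contact_preload])
    ligaments = []
    for name in LIGAMENT_NAMES:
        a, b_neutral, A, B = _DEFAULT_TABLE[name]
        a = np.asarray(a) * s
        b_neutral = np.asarray(b_neutral) * s
        ligaments.append(
            Ligament2D(
                name=name,
                a=a,
                b_local=b_neutral - p0,
                l_slack=float(np.linalg.norm(b_neutral - a)),
                A=A,
                B=B,
            )
        )
    contact = ContactPair(
        O_a=np.zeros(2),
        O_b_local=np.zeros(2),
        r_a=spec.r_a * s,
        r_b=spec.r_b * s,
        E=spec.E,
        nu=spec.nu,
        multiplicity=2,
    )
    return JointModel(
        ligaments=ligaments,
        contacts=[contact],
        force_model=spec.force_model,
        name="default planar ankle fixture",
        neutral_state=JointState(0.0, p0),
        solver=SolverSettings(),
    )


def synthetic_ligament3d(
    in_plane_angle_deg: float,
    out_of_plane_angle_deg: float,
    slack: float,
    A: float,
    B: float,
    name: str = "synthetic",
) -> Ligament3D:
    """A straight 3-D ligament for fine-tuning tests.

    The cable axis makes ``out_of_plane_angle_deg`` with the sagittal (x-y)
    plane and its in-plane component makes ``in_plane_angle_deg`` with the
    x axis.  ``out_of_plane_angle_deg = 0`` gives an in-plane ligament (the
    identity fitting case); the projected slack length is
    ``slack * cos(out_of_plane_angle)``.  Nearly-frontal ligaments such as
    ATF (2.19 deg off the frontal z axis) correspond to out-of-plane angles
    near 90 deg.
    """
    if not (slack > 0):
        raise ValueError("slack must be > 0")
    ip = math.radians(in_plane_angle_deg)
    oop = math.radians(out_of_plane_angle_deg)
    direction = np.array(
        [math.cos(oop) * math.cos(ip), math.cos(oop) * math.sin(ip), math.sin(oop)]
    )
    a3 = np.zeros(3)
    return Ligament3D(
        name=name,
        a3=a3,
        b3_local=a3 + slack * direction,
        l_slack3=float(slack),
        A3=float(A),
        B3=float(B),
    )


def perturb_attachment(
    model: JointModel,
    ligament_name: str,
    delta,
    side: str = "basis",
    recompute_slack: bool = False,
) -> JointModel:
    """Return a copy of the model with one attachment translated by ``delta``.

    ``side`` selects the basis-frame attachment (``"basis"``, the TFS side)
    or the moving-frame one (``"moving"``).  By default the slack length is
    NOT recomputed: the perturbation pre-strains or slackens the ligament,
    which is exactly what a geometric sensitivity test probes.  Passing
    ``recompute_slack=True`` instead re-zeroes the strain at neutral.
    The original model is untouched.
    """
    if side not in ("basis", "moving"):
        raise ValueError(f"side must be 'basis' or 'moving', got {side!r}")
    delta = np.asarray(delta, dtype=float)
    new_model = copy.deepcopy(model)
    for i, lig in enumerate(new_model.ligaments):
        if lig.name == ligament_name:
            a = lig.a + delta if side == "basis" else lig.a
            b_local = lig.b_local + delta if side == "moving" else lig.b_local
            if recompute_slack:
                from .ligaments import ligament_length

                probe = Ligament2D(lig.name, a, b_local, lig.l_slack, lig.A, lig.B)
                l_slack = ligament_length(probe, new_model.neutral_state)
            else:
                l_slack = lig.l_slack
            new_model.ligaments[i] = Ligament2D(
                name=lig.name, a=a, b_local=b_local, l_slack=l_slack, A=lig.A, B=lig.B
            )
            return new_model
    raise KeyError(
        f"no ligament named {ligament_name!r}; have {model.ligament_names}"
    )
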
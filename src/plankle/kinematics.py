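"""Planar rigid-body kinematics for the two-segment ankle model.

The talocrural joint is reduced to two rigid bodies working in the sagittal
plane: a fixed basis, the tibia-fibula segment (TFS), and a moving body, the
talus-calcaneus segment (TCS).  The moving body is located by three
generalized coordinates: one rotation angle ``theta`` and the two components
of the position vector ``p`` of the moving-frame origin expressed in the
basis frame.

Conventions
-----------
* lengths in millimetres, angles in radians internally (degrees only at the
  I/O boundary);
* ``x``-``y`` span the sagittal plane; the out-of-plane ``z`` axis (used only
  by the 3-D ligaments in :mod:`plankle.finetune`) is the horizontal axis of
  the frontal plane;
* ``theta`` is counter-clockwise positive; in the default fixture a positive
  external moment (plantarflexion) drives ``theta`` positive, a negative
  moment (dorsiflexion) drives it negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "JointState",
    "rotation_matrix",
    "to_basis_frame",
    "to_local_frame",
    "as_vec2",
    "as_vec3",
]


def as_vec2(x, name: str = "point") -> np.ndarray:
    """Coerce ``x`` to a finite float vector of shape ``(2,)``."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.shape != (2,):
        raise ValueError(f"{name} must be a 2-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


def as_vec3(x, name: str = "point") -> np.ndarray:
    """Coerce ``x`` to a finite float vector of shape ``(3,)``."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


@dataclass(frozen=True)
class JointState:
    """Location of the moving body (TCS) relative to the basis (TFS).

    Parameters
    ----------
    theta : float
        Rotation angle from the moving frame to the basis frame, radians,
        counter-clockwise positive.  Restricted to ``|theta| < pi``: the
        model describes a physiological joint, not a full revolution.
    p : (2,) array_like
        Position of the moving-frame origin in the basis frame, mm.
    """

    theta: float
    p: np.ndarray

    def __post_init__(self):
        theta = float(self.theta)
        if not math.isfinite(theta):
            raise ValueError("theta must be finite")
        if abs(theta) >= math.pi:
            raise ValueError(
                f"|theta| must be < pi (physiological joint rotation), got {theta}"
            )
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "p", as_vec2(self.p, "p"))

    def as_array(self) -> np.ndarray:
        """Pack the generalized coordinates as ``[theta, px, py]``."""
        return np.array([self.theta, self.p[0], self.p[1]])

    @classmethod
    def from_array(cls, x) -> "JointState":
        x = np.asarray(x, dtype=float)
        return cls(float(x[0]), x[1:3].copy())


def rotation_matrix(theta: float) -> np.ndarray:
    """Planar rotation matrix from the moving (TCS) frame to the basis (TFS).

    Returns ``[[cos t, -sin t], [sin t, cos t]]``; orthonormal with
    determinant +1.
    """
    theta = float(theta)
    if not math.isfinite(theta):
        raise ValueError("theta must be finite")
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def to_basis_frame(point_local, state: JointState) -> np.ndarray:
    """Express a point given in the moving frame in the basis frame.

    Implements the rigid-body transform ``R(theta) @ point_local + p``.
    """
    return rotation_matrix(state.theta) @ as_vec2(point_local, "point_local") + state.p


def to_local_frame(point_basis, state: JointState) -> np.ndarray:
    """Inverse of :func:`to_basis_frame`."""
    return rotation_matrix(state.theta).T @ (
        as_vec2(point_basis, "point_basis") - state.p
    )
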
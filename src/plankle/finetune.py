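"""Fine-tuning planar cable coefficients against 3-D ligaments.

A real ankle ligament is a spatial cable; a sagittal-plane model replaces it
with a planar cable obtained by dropping the out-of-plane (z) coordinate of
both attachments.  For oblique ligaments this projection distorts strains
badly: a nearly-frontal ligament has a tiny in-plane slack length, so small
sagittal displacements produce enormous planar strains while the true 3-D
ligament barely stretches.  Material coefficients measured on the 3-D
ligament therefore cannot be reused directly in the plane.

The remedy implemented here: displace the moving segment through a small
protocol of in-plane translations (by default +/-4 mm along y and along x,
four displacements in total), record for each displacement the magnitude of
the sagittal projection of the 3-D ligament force and the strain of the
planar substitute, and fit the planar coefficients ``(A, B)`` so the planar
exponential law reproduces the projected forces in the least-squares sense.
The fit modifies only material parameters; the geometry is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import DegenerateGeometryError, UnfittableProblemError
from .kinematics import as_vec3
from .ligaments import FORCE_MODELS, force_magnitude

__all__ = [
    "DEFAULT_DISPLACEMENT_MM",
    "Ligament3D",
    "PlanarCableGeometry",
    "FitProblem",
    "FitResult",
    "default_protocol",
    "project_to_sagittal",
    "sagittal_force_magnitude",
    "build_fit_problem",
    "build_residual_system",
    "fit_material_params",
    "fit_report",
]

DEFAULT_DISPLACEMENT_MM = 4.0

_MIN_LENGTH = 1e-12


@dataclass(frozen=True)
class Ligament3D:
    """A spatial ligament cable in its unloaded (neutral) configuration.

    ``a3`` is the basis-side attachment and ``b3_local`` the moving-side
    attachment; at neutral the moving frame coincides with the basis frame,
    so ``b3_local`` is also the basis-frame position of the moving
    attachment.  Coordinates in mm; z is the out-of-sagittal-plane axis.
    """

    name: str
    a3: np.ndarray
    b3_local: np.ndarray
    l_slack3: float
    A3: float
    B3: float

    def __post_init__(self):
        object.__setattr__(self, "a3", as_vec3(self.a3, f"{self.name}.a3"))
        object.__setattr__(self, "b3_local", as_vec3(self.b3_local, f"{self.name}.b3_local"))
        if not (self.l_slack3 > 0):
            raise ValueError(f"{self.name}: l_slack3 must be > 0, got {self.l_slack3}")
        if not (self.A3 >= 0):
            raise ValueError(f"{self.name}: A3 must be >= 0, got {self.A3}")
        if not (self.B3 > 0):
            raise ValueError(f"{self.name}: B3 must be > 0, got {self.B3}")


@dataclass(frozen=True)
class PlanarCableGeometry:
    """Sagittal projection of a 3-D ligament: attachments with the
    out-of-plane coordinate dropped and the slack length recomputed
    in-plane at the neutral configuration.  Material coefficients are left
    to the fit."""

    name: str
    a: np.ndarray
    b_local: np.ndarray
    l_slack: float


def default_protocol(displacement_mm: float = DEFAULT_DISPLACEMENT_MM) -> np.ndarray:
    """The four-displacement protocol: +/-d along y, +/-d along x (in-plane
    translations of the moving segment, no rotation)."""
    d = float(displacement_mm)
    if not (d > 0):
        raise ValueError("displacement magnitude must be > 0")
    return np.array(
        [[0.0, d, 0.0], [0.0, -d, 0.0], [d, 0.0, 0.0], [-d, 0.0, 0.0]]
    )


def project_to_sagittal(lig3d: Ligament3D) -> PlanarCableGeometry:
    """Drop the out-of-plane coordinate of both attachments.

    The planar slack length is the in-plane attachment distance at neutral,
    following the convention that slack lengths are computed at the neutral
    location.
    """
    a = lig3d.a3[:2].copy()
    b = lig3d.b3_local[:2].copy()
    l_slack = float(np.linalg.norm(b - a))
    if l_slack < _MIN_LENGTH:
        raise DegenerateGeometryError(
            f"{lig3d.name}: attachments project onto the same sagittal point; "
            "the planar substitute is degenerate"
        )
    return PlanarCableGeometry(name=lig3d.name, a=a, b_local=b, l_slack=l_slack)


def _force3d_vector(lig3d: Ligament3D, displacement, force_model: str) -> np.ndarray:
    d = as_vec3(displacement, "displacement")
    b = lig3d.b3_local + d
    axis = b - lig3d.a3
    length = float(np.linalg.norm(axis))
    if length < _MIN_LENGTH:
        raise DegenerateGeometryError(
            f"{lig3d.name}: attachments coincide under this displacement"
        )
    eps = (length - lig3d.l_slack3) / lig3d.l_slack3
    if eps <= 0.0:
        return np.zeros(3)
    value = force_magnitude(lig3d.A3, lig3d.B3, eps, force_model)
    return -(axis / length) * value


def sagittal_force_magnitude(
    lig3d: Ligament3D, displacement, force_model: str = "exp_shifted"
) -> float:
    """Magnitude of the sagittal projection of the 3-D ligament force under a
    pure translation of the moving segment (N).

    The 3-D force is evaluated with the spatial form of the cable equations;
    its out-of-plane component is zeroed and the in-plane magnitude
    returned.  A slack ligament yields 0; an in-plane ligament yields the
    full 3-D force magnitude.
    """
    f = _force3d_vector(lig3d, displacement, force_model)
    return float(np.hypot(f[0], f[1]))


@dataclass(frozen=True)
class FitProblem:
    """Precomputed residual data for one ligament fit.

    One residual per displacement: planar strain of the projected geometry
    and sagittal force target of the 3-D ligament under the same in-plane
    translation.  ``fittable`` is False when no displacement activates the
    planar cable (all strains <= 0), which leaves (A, B) unidentifiable.
    """

    lig3d: Ligament3D
    geometry: PlanarCableGeometry
    displacements: np.ndarray
    strains_2d: np.ndarray
    targets: np.ndarray
    force_model: str
    fittable: bool


def build_fit_problem(
    lig3d: Ligament3D,
    displacements=None,
    force_model: str = "exp_shifted",
) -> FitProblem:
    """Assemble strains and force targets over the displacement protocol."""
    if force_model not in FORCE_MODELS:
        raise ValueError(f"unknown force_model {force_model!r}; choose from {FORCE_MODELS}")
    disp = (
        default_protocol()
        if displacements is None
        else np.atleast_2d(np.asarray(displacements, dtype=float))
    )
    if disp.shape[1] != 3 or not np.all(np.isfinite(disp)):
        raise ValueError("displacements must be finite 3-vectors")
    geom = project_to_sagittal(lig3d)
    strains = np.empty(len(disp))
    targets = np.empty(len(disp))
    for j, d in enumerate(disp):
        length = float(np.linalg.norm(geom.b_local + d[:2] - geom.a))
        strains[j] = (length - geom.l_slack) / geom.l_slack
        targets[j] = sagittal_force_magnitude(lig3d, d, force_model)
    return FitProblem(
        lig3d=lig3d,
        geometry=geom,
        displacements=disp,
        strains_2d=strains,
        targets=targets,
        force_model=force_model,
        fittable=bool(np.any(strains > 0.0)),
    )


def build_residual_system(problem: FitProblem):
    """Return the residual function ``res(params) -> (n_disp,)``.

    ``res_j = F_2D(A, B, eps_2D_j) - F_3D/sag_j`` with the planar force
    following the selected force model, including its slack branch (zero
    force at non-positive strain).
    """
    strains = problem.strains_2d
    targets = problem.targets
    model = problem.force_model

    def residuals(params):
        A, B = params
        return force_magnitude(A, B, strains, model) - targets

    return residuals


@dataclass(frozen=True)
class FitResult:
    """Fitted planar coefficients with diagnostics."""

    name: str
    A: float
    B: float
    A_initial: float
    B_initial: float
    residual_norm: float
    residuals: np.ndarray
    fitted_forces: np.ndarray
    strains_2d: np.ndarray
    targets: np.ndarray
    success: bool
    message: str


def fit_material_params(
    problem: FitProblem, initial=None
) -> FitResult:
    """Least-squares fit of (A, B) to the sagittal force targets.

    Bounded to ``A >= 0, B > 0``; the default initial guess is the 3-D
    ligament's experimental coefficients.  Deterministic given the initial
    guess.  Raises :class:`UnfittableProblemError` when no displacement
    activates the planar cable.
    """
    if not problem.fittable:
        raise UnfittableProblemError(
            f"{problem.lig3d.name}: no protocol displacement activates the planar "
            "cable (all planar strains <= 0); (A, B) are unidentifiable"
        )
    if initial is None:
        initial = (problem.lig3d.A3, problem.lig3d.B3)
    A0, B0 = float(initial[0]), float(initial[1])
    if not (A0 > 0 and B0 > 0):
        raise ValueError(f"initial guess must be positive, got A={A0}, B={B0}")
    residuals = build_residual_system(problem)
    sol = least_squares(
        residuals,
        x0=[A0, B0],
        bounds=([0.0, 1e-12], [np.inf, np.inf]),
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=5000,
    )
    res = residuals(sol.x)
    A, B = float(sol.x[0]), float(sol.x[1])
    return FitResult(
        name=problem.lig3d.name,
        A=A,
        B=B,
        A_initial=A0,
        B_initial=B0,
        residual_norm=float(np.linalg.norm(res)),
        residuals=res,
        fitted_forces=force_magnitude(A, B, problem.strains_2d, problem.force_model),
        strains_2d=problem.strains_2d.copy(),
        targets=problem.targets.copy(),
        success=bool(sol.success),
        message=str(sol.message),
    )


def fit_report(results) -> pd.DataFrame:
    """Tabulate fit results: coefficients, residual norm and the
    per-displacement strain/target/fitted-force triples."""
    rows = []
    for r in results:
        row = {
            "ligament": r.name,
            "A_initial": r.A_initial,
            "B_initial": r.B_initial,
            "A_fitted": r.A,
            "B_fitted": r.B,
            "residual_norm": r.residual_norm,
        }
        for j in range(len(r.strains_2d)):
            row[f"strain_2d_disp{j + 1}"] = r.strains_2d[j]
            row[f"target_force_n_disp{j + 1}"] = r.targets[j]
            row[f"fitted_force_n_disp{j + 1}"] = r.fitted_forces[j]
        rows.append(row)
    return pd.DataFrame(rows)
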
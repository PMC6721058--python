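"""Static equilibrium of the moving body under external loads.

The residual stacks the force and moment balance of the moving body::

    r = [ sum Fx + Fext_x ,  sum Fy + Fext_y ,  (sum M + Mext) ]

with ligament and contact forces in N and all moments taken about the
basis-frame origin.  Following the convention that external moments are
quoted in N*m while the geometry is millimetre-scale, the moment component
of the reported residual is expressed in N*m so that the acceptance rule
(sum of absolute residual components below ``tolerance``, default 1e-10)
is meaningful at both scales.

Equilibria are found with Levenberg-Marquardt on the 3-vector residual,
warm-started along load sweeps (continuation outward from zero load).
Statics may admit multiple equilibria; the solver reports the one reached
by continuation from the supplied initial state.
"""

from __future__ import annotations

import logging
import math
from collections import namedtuple
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .contacts import ContactPair, contact_energy, contact_load
from .exceptions import NumericalError
from .kinematics import JointState, as_vec2
from .ligaments import FORCE_MODELS, Ligament2D, ligament_energy, ligament_force

__all__ = [
    "SolverSettings",
    "JointModel",
    "LoadCase",
    "EquilibriumResult",
    "SweepTable",
    "residual",
    "residual_norm_value",
    "total_elastic_potential",
    "total_potential",
    "solve_equilibrium",
    "sweep_moments",
]

# Lightweight stand-in for JointState used inside the solver loop, where
# trial iterates may transiently violate the |theta| < pi invariant.
_log = logging.getLogger(__name__)

_RawState = namedtuple("_RawState", ["theta", "p"])

RESIDUAL_NORMS = ("sum_abs", "l2")


@dataclass
class SolverSettings:
    """Levenberg-Marquardt settings.

    ``tolerance`` applies to the residual norm in mixed units (N, N, N*m);
    ``residual_norm`` selects between the sum of absolute components
    (default) and the Euclidean norm.  When a solve stalls (the force-law
    discontinuity of the as-printed exponential model can do this at
    activation boundaries), up to ``retries`` restarts are attempted from
    deterministically jittered initial states seeded by ``seed``.
    """

    tolerance: float = 1e-10
    residual_norm: str = "sum_abs"
    max_nfev: int = 2000
    retries: int = 8
    jitter_theta: float = 0.05  # rad
    jitter_p: float = 0.5  # mm
    seed: int = 12345

    def __post_init__(self):
        if self.residual_norm not in RESIDUAL_NORMS:
            raise ValueError(
                f"residual_norm must be one of {RESIDUAL_NORMS}, got {self.residual_norm!r}"
            )
        if not (self.tolerance > 0):
            raise ValueError("tolerance must be > 0")


@dataclass
class JointModel:
    """A complete planar joint: ligament set, contact set, conventions."""

    ligaments: list
    contacts: list
    force_model: str = "exp_shifted"
    name: str = "joint model"
    neutral_state: JointState = field(
        default_factory=lambda: JointState(0.0, np.zeros(2))
    )
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self):
        if self.force_model not in FORCE_MODELS:
            raise ValueError(
                f"force_model must be one of {FORCE_MODELS}, got {self.force_model!r}"
            )
        for lig in self.ligaments:
            if not isinstance(lig, Ligament2D):
                raise TypeError(f"ligaments must be Ligament2D, got {type(lig)}")
        for pair in self.contacts:
            if not isinstance(pair, ContactPair):
                raise TypeError(f"contacts must be ContactPair, got {type(pair)}")

    @property
    def n_ligaments(self) -> int:
        return len(self.ligaments)

    @property
    def effective_contact_count(self) -> int:
        """Number of physical contact pairs, counting multiplicities."""
        return sum(pair.multiplicity for pair in self.contacts)

    @property
    def ligament_names(self) -> list:
        return [lig.name for lig in self.ligaments]

    def ligament(self, name: str) -> Ligament2D:
        for lig in self.ligaments:
            if lig.name == name:
                return lig
        raise KeyError(f"no ligament named {name!r}; have {self.ligament_names}")


@dataclass(frozen=True)
class LoadCase:
    """External load on the moving body: force in N, moment in N*m."""

    F_ext: np.ndarray
    M_ext: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "F_ext", as_vec2(self.F_ext, "F_ext"))
        if not np.isfinite(self.M_ext):
            raise ValueError(f"M_ext must be finite, got {self.M_ext}")
        object.__setattr__(self, "M_ext", float(self.M_ext))

    @property
    def M_ext_nmm(self) -> float:
        """External moment converted to internal units, N*mm."""
        return self.M_ext * 1000.0

    @classmethod
    def pure_moment(cls, M_ext_nm: float) -> "LoadCase":
        return cls(np.zeros(2), M_ext_nm)


def _element_loads(state, model: JointModel):
    lig_loads = [ligament_force(l, state, model.force_model) for l in model.ligaments]
    con_loads = [contact_load(c, state) for c in model.contacts]
    return lig_loads, con_loads


def _residual_from_loads(lig_loads, con_loads, load: LoadCase) -> np.ndarray:
    F = load.F_ext.copy()
    M = load.M_ext_nmm
    for ld in lig_loads:
        F = F + ld.force_vector
        M += ld.moment
    for ld in con_loads:
        F = F + ld.force_vector
        M += ld.moment
    return np.array([F[0], F[1], M / 1000.0])


def residual(state, model: JointModel, load: LoadCase) -> np.ndarray:
    """Equilibrium residual ``(sum Fx [N], sum Fy [N], sum M [N*m])``.

    Includes the external load; all internal moments are taken about the
    basis-frame origin.
    """
    lig_loads, con_loads = _element_loads(state, model)
    return _residual_from_loads(lig_loads, con_loads, load)


def residual_norm_value(r: np.ndarray, convention: str = "sum_abs") -> float:
    if convention == "sum_abs":
        return float(np.sum(np.abs(r)))
    if convention == "l2":
        return float(np.linalg.norm(r))
    raise ValueError(f"unknown residual norm convention {convention!r}")


def total_elastic_potential(model: JointModel, state) -> float:
    """Total elastic potential (ligaments + contacts) at a state, N*mm."""
    U = 0.0
    for lig in model.ligaments:
        U += ligament_energy(lig, state, model.force_model)
    for pair in model.contacts:
        U += contact_energy(pair, state)
    return U


def total_potential(model: JointModel, state, load: LoadCase) -> float:
    """Potential of the loaded system, N*mm.

    ``Pi = U_elastic - F_ext . p - M_ext * theta``.  For a pure-moment load
    every equilibrium is a stationary point of ``Pi``; stable equilibria are
    local minima.
    """
    return (
        total_elastic_potential(model, state)
        - float(load.F_ext @ state.p)
        - load.M_ext_nmm * state.theta
    )


@dataclass
class EquilibriumResult:
    """Outcome of one static solve."""

    state: JointState
    residual: np.ndarray  # (Fx N, Fy N, M N*m)
    residual_norm: float
    converged: bool
    ligament_loads: list
    contact_loads: list
    nfev: int
    attempts: int

    def summary(self) -> dict:
        return {
            "theta_deg": float(np.degrees(self.state.theta)),
            "px_mm": float(self.state.p[0]),
            "py_mm": float(self.state.p[1]),
            "residual_norm": self.residual_norm,
            "converged": self.converged,
        }


def solve_equilibrium(
    model: JointModel, load: LoadCase, initial: JointState | None = None
) -> EquilibriumResult:
    """Find a moving-body location balancing the external load.

    Levenberg-Marquardt on the 3-vector residual, accepted when the residual
    norm (default: sum of absolute components in N, N, N*m) falls below the
    solver tolerance.  Non-convergence is reported via ``converged=False``,
    never silently.
    """
    if model.n_ligaments == 0 and not model.contacts:
        raise ValueError("model has no load-bearing elements; equilibrium is undefined")
    start = initial if initial is not None else model.neutral_state
    x0 = start.as_array()

    def fun(x):
        r = residual(_RawState(x[0], x[1:3]), model, load)
        if np.any(np.isnan(r)):
            raise NumericalError(f"residual is NaN at state {x}")
        return r

    settings = model.solver
    rng = np.random.default_rng(settings.seed)
    jitter_scale = np.array([settings.jitter_theta, settings.jitter_p, settings.jitter_p])
    best_x, best_r, best_norm, best_nfev = None, None, np.inf, 0
    attempts = 0
    for attempt in range(settings.retries + 1):
        attempts += 1
        xs = x0 if attempt == 0 else x0 + rng.normal(size=3) * jitter_scale * attempt
        sol = least_squares(
            fun,
            xs,
            method="lm",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=settings.max_nfev,
        )
        r = fun(sol.x)
        norm = residual_norm_value(r, settings.residual_norm)
        if norm < best_norm:
            best_x, best_r, best_norm, best_nfev = sol.x, r, norm, sol.nfev
        if best_norm < settings.tolerance:
            break
    # The residual is 2*pi-periodic in theta; wrap the solved angle back
    # into the physiological branch before building the validated state.
    best_x = best_x.copy()
    best_x[0] = math.remainder(best_x[0], 2.0 * math.pi)
    state = JointState.from_array(best_x)
    lig_loads, con_loads = _element_loads(state, model)
    return EquilibriumResult(
        state=state,
        residual=best_r,
        residual_norm=best_norm,
        converged=best_norm < settings.tolerance,
        ligament_loads=lig_loads,
        contact_loads=con_loads,
        nfev=best_nfev,
        attempts=attempts,
    )


# Continuation guards for sweep_moments.  At the unloaded neutral state of a
# slack-everywhere fixture every cable sits exactly at its activation kink,
# where a finite-difference Jacobian is meaningless; nudging the start of a
# branch a fraction of a degree in the direction the moment will rotate the
# body moves the linearization to a smooth point.  The continuity limit
# detects a converged-but-disconnected equilibrium (statics admits multiple
# solutions); the branch is then re-walked with adaptive load substeps.
_BRANCH_NUDGE_RAD = 0.01
_CONTINUITY_LIMIT_RAD = 0.35
_MAX_SUBSTEP_DEPTH = 10


def _nudged(state: JointState, moment_sign_nm: float) -> JointState:
    if moment_sign_nm == 0.0:
        return state
    theta = state.theta + math.copysign(_BRANCH_NUDGE_RAD, moment_sign_nm)
    return JointState(theta, state.p)


def _solve_near(
    model: JointModel, load: LoadCase, start: JointState, nudge_sign: float
) -> EquilibriumResult:
    """Solve, preferring an equilibrium close to ``start``.

    A plain solve that converges far away (a basin jump near an activation
    kink, where finite-difference Jacobians degrade) is retried from
    deterministically jittered starts; the closest converged solution wins.
    """
    def near(res):
        return abs(res.state.theta - start.theta) <= _CONTINUITY_LIMIT_RAD

    first = solve_equilibrium(model, load, initial=_nudged(start, nudge_sign))
    if first.converged and near(first):
        return first
    rng = np.random.default_rng(model.solver.seed + 1)
    best_near = first if near(first) else None
    scale = np.array([0.02, 0.2, 0.2])
    shallow = replace(model, solver=replace(model.solver, retries=2))
    for _ in range(12):
        x = start.as_array() + rng.normal(size=3) * scale
        x[0] += nudge_sign and math.copysign(_BRANCH_NUDGE_RAD, nudge_sign)
        cand = solve_equilibrium(shallow, load, initial=JointState.from_array(
            np.clip(x, [-3.1, -1e6, -1e6], [3.1, 1e6, 1e6])))
        if near(cand):
            if cand.converged:
                return cand
            if best_near is None or cand.residual_norm < best_near.residual_norm:
                best_near = cand
    # No converged equilibrium in this basin.  A converged-but-distant root
    # belongs to a different branch and would silently teleport the
    # continuation, so prefer the honest near-stall.
    return best_near if best_near is not None else first


def _continue_branch(
    model: JointModel, from_state: JointState, m_from: float, m_to: float
) -> EquilibriumResult:
    """Walk the equilibrium branch from ``m_from`` to ``m_to`` (N*m) with
    bisection substeps whenever a step fails or jumps basins."""
    state = from_state
    m = m_from
    pending = [m_to]
    depth = 0
    res = None
    while pending:
        target = pending[-1]
        res = _solve_near(model, LoadCase.pure_moment(target), state, target - m)
        ok = res.converged and abs(res.state.theta - state.theta) <= _CONTINUITY_LIMIT_RAD
        if ok:
            pending.pop()
            state = res.state
            m = target
        else:
            depth += 1
            if depth > _MAX_SUBSTEP_DEPTH:
                # Give up: either no equilibrium on this branch segment or a
                # persistent basin jump; report the step as not followed.
                res.converged = False
                return res
            pending.append(0.5 * (m + target))
    return res


@dataclass
class SweepTable:
    """Equilibria along a moment grid, one row per converged grid point.

    ``partial`` is set when a branch aborted at a non-converged step (rows
    beyond the failure are not computed).
    """

    ligament_names: list
    moments_nm: list
    results: list
    neutral_theta: float
    partial: bool

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m, res in zip(self.moments_nm, self.results):
            row = {
                "m_ext_nm": m,
                "dtheta_deg": float(np.degrees(res.state.theta - self.neutral_theta)),
                "px_mm": float(res.state.p[0]),
                "py_mm": float(res.state.p[1]),
            }
            for name, ld in zip(self.ligament_names, res.ligament_loads):
                row[f"strain_{name}_pct"] = 100.0 * ld.strain
                row[f"force_{name}_n"] = ld.force_value
            row["force_contact_n"] = float(
                sum(ld.force_value for ld in res.contact_loads)
            )
            row["converged"] = res.converged
            rows.append(row)
        columns = ["m_ext_nm", "dtheta_deg", "px_mm", "py_mm"]
        for name in self.ligament_names:
            columns += [f"strain_{name}_pct", f"force_{name}_n"]
        columns += ["force_contact_n", "converged"]
        return pd.DataFrame(rows, columns=columns)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> dict:
        """Ranges, per-ligament strain/force statistics, peak contact force."""
        df = self.to_dataframe()
        conv = df[df["converged"]]
        if len(conv) == 0:
            dorsi = plantar = 0.0
        else:
            dorsi = max(0.0, -float(conv["dtheta_deg"].min()))
            plantar = max(0.0, float(conv["dtheta_deg"].max()))
        ligs = {}
        for name in self.ligament_names:
            s = conv[f"strain_{name}_pct"] if len(conv) else pd.Series(dtype=float)
            f = conv[f"force_{name}_n"] if len(conv) else pd.Series(dtype=float)
            ligs[name] = {
                "peak_strain_pct": float(s.max()) if len(s) else float("nan"),
                "mean_abs_strain_pct": float(s.abs().mean()) if len(s) else float("nan"),
                "peak_force_n": float(f.max()) if len(f) else float("nan"),
            }
        return {
            "dorsiflexion_range_deg": dorsi,
            "plantarflexion_range_deg": plantar,
            "total_range_deg": dorsi + plantar,
            "ligaments": ligs,
            "peak_contact_force_n": (
                float(conv["force_contact_n"].max()) if len(conv) else float("nan")
            ),
            "all_converged": bool(df["converged"].all()) and not self.partial,
            "partial": self.partial,
            "n_points_computed": int(len(df)),
        }


def sweep_moments(
    model: JointModel,
    moment_grid_nm,
    warm_start: bool = True,
    initial: JointState | None = None,
) -> SweepTable:
    """Solve a grid of pure-moment load cases (N*m).

    The sweep proceeds outward from zero load in each direction: the zero
    (or anchor) solve starts from the model's neutral state and each branch
    continues with warm starts from the previous grid point.  A
    non-converged step aborts its branch and flags the table as partial.
    Rows are returned in ascending moment order.
    """
    grid = np.asarray(moment_grid_nm, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or not np.all(np.isfinite(grid)):
        raise ValueError("moment grid must be a non-empty finite 1-D sequence (N*m)")
    base = initial if initial is not None else model.neutral_state
    anchor = _solve_near(model, LoadCase.pure_moment(0.0), base, 0.0)

    order = np.argsort(grid, kind="stable")
    pos_idx = [i for i in order if grid[i] > 0]
    neg_idx = [i for i in reversed(order) if grid[i] < 0]
    zero_idx = [i for i in order if grid[i] == 0]

    results = {}
    partial = not anchor.converged
    for i in zero_idx:
        results[int(i)] = anchor
    anchor_state = anchor.state if anchor.converged else base
    for branch in (pos_idx, neg_idx):
        prev = anchor_state
        prev_m = 0.0
        for i in branch:
            start = _nudged(prev, grid[i] - prev_m) if warm_start else _nudged(
                anchor_state, grid[i]
            )
            res = solve_equilibrium(model, LoadCase.pure_moment(grid[i]), initial=start)
            if warm_start and (
                not res.converged
                or abs(res.state.theta - prev.theta) > _CONTINUITY_LIMIT_RAD
            ):
                res = _continue_branch(model, prev, prev_m, grid[i])
            results[int(i)] = res
            _log.debug(
                "sweep M=%+.4f N*m: theta=%.6f rad, residual=%.3e (%d evals, "
                "%d attempts, converged=%s)",
                grid[i], res.state.theta, res.residual_norm, res.nfev,
                res.attempts, res.converged,
            )
            if not res.converged:
                partial = True
                break
            if warm_start:
                prev = res.state
                prev_m = float(grid[i])

    computed = [int(i) for i in order if int(i) in results]
    return SweepTable(
        ligament_names=model.ligament_names,
        moments_nm=[float(grid[i]) for i in computed],
        results=[results[i] for i in computed],
        neutral_theta=model.neutral_state.theta,
        partial=partial,
    )
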
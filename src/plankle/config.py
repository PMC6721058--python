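"""Schema-validated JSON model configs.

A model config is a single JSON document with an explicit ``units`` block;
angles are degrees and external moments N*m at this I/O boundary (radians
and N*mm internally).  Unknown keys are rejected with a named error and
invariants (positive slack lengths, ``r_a > r_b``, ...) are checked at load
time, not at solve time.  Serialization is deterministic (sorted keys), so
round trips are byte-identical.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import List, Literal, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .contacts import ContactPair
from .kinematics import JointState
from .ligaments import Ligament2D
from .statics import JointModel, SolverSettings

__all__ = [
    "ModelConfig",
    "load_model",
    "save_model",
    "to_joint_model",
    "from_joint_model",
    "models_equal",
]


class _Cfg(BaseModel):
    model_config = ConfigDict(extra="forbid")


class UnitsConfig(_Cfg):
    """Declared unit conventions; fixed in this release."""

    length: Literal["mm"] = "mm"
    force: Literal["N"] = "N"
    moment_io: Literal["N*m"] = "N*m"
    angle_io: Literal["deg"] = "deg"


class LigamentConfig(_Cfg):
    name: str
    a: Tuple[float, float]
    b_local: Tuple[float, float]
    l_slack: float = Field(gt=0)
    A: float = Field(ge=0)
    B: float = Field(gt=0)


class ContactConfig(_Cfg):
    O_a: Tuple[float, float]
    O_b_local: Tuple[float, float]
    r_a: float = Field(gt=0)
    r_b: float = Field(gt=0)
    E: float = Field(gt=0)
    nu: float = Field(ge=0, lt=0.5)
    multiplicity: int = Field(default=1, ge=1)

    @model_validator(mode="after")
    def _female_strictly_larger(self):
        if self.r_a <= self.r_b:
            raise ValueError(
                f"r_a must be strictly greater than r_b (female sphere larger); "
                f"got r_a={self.r_a}, r_b={self.r_b}"
            )
        return self


class NeutralConfig(_Cfg):
    theta_deg: float = 0.0
    p: Tuple[float, float] = (0.0, 0.0)


class SolverConfig(_Cfg):
    tolerance: float = Field(default=1e-10, gt=0)
    residual_norm: Literal["sum_abs", "l2"] = "sum_abs"
    max_nfev: int = Field(default=2000, ge=1)
    retries: int = Field(default=8, ge=0)
    jitter_theta: float = Field(default=0.05, ge=0)
    jitter_p: float = Field(default=0.5, ge=0)
    seed: int = 12345


class SweepConfig(_Cfg):
    moment_range_nm: float = Field(default=5.0, gt=0)
    steps: int = Field(default=51, ge=2)
    warm_start: bool = True


class ModelConfig(_Cfg):
    """Top-level model document."""

    name: str = "joint model"
    units: UnitsConfig = Field(default_factory=UnitsConfig)
    force_model: Literal["exp_shifted", "exp_minus_one"] = "exp_shifted"
    neutral: NeutralConfig = Field(default_factory=NeutralConfig)
    ligaments: List[LigamentConfig] = Field(default_factory=list)
    contacts: List[ContactConfig] = Field(default_factory=list)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    sweep: SweepConfig = Field(default_factory=SweepConfig)

    def dumps(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True) + "\n"

    @classmethod
    def loads(cls, text: str) -> "ModelConfig":
        return cls.model_validate(json.loads(text))


def to_joint_model(cfg: ModelConfig) -> JointModel:
    """Materialize a validated config into the runtime model (degrees ->
    radians at this boundary)."""
    ligaments = [
        Ligament2D(
            name=l.name,
            a=np.asarray(l.a),
            b_local=np.asarray(l.b_local),
            l_slack=l.l_slack,
            A=l.A,
            B=l.B,
        )
        for l in cfg.ligaments
    ]
    contacts = [
        ContactPair(
            O_a=np.asarray(c.O_a),
            O_b_local=np.asarray(c.O_b_local),
            r_a=c.r_a,
            r_b=c.r_b,
            E=c.E,
            nu=c.nu,
            multiplicity=c.multiplicity,
        )
        for c in cfg.contacts
    ]
    solver = SolverSettings(
        tolerance=cfg.solver.tolerance,
        residual_norm=cfg.solver.residual_norm,
        max_nfev=cfg.solver.max_nfev,
        retries=cfg.solver.retries,
        jitter_theta=cfg.solver.jitter_theta,
        jitter_p=cfg.solver.jitter_p,
        seed=cfg.solver.seed,
    )
    return JointModel(
        ligaments=ligaments,
        contacts=contacts,
        force_model=cfg.force_model,
        name=cfg.name,
        neutral_state=JointState(math.radians(cfg.neutral.theta_deg), np.asarray(cfg.neutral.p)),
        solver=solver,
    )


def from_joint_model(model: JointModel, sweep: SweepConfig | None = None) -> ModelConfig:
    return ModelConfig(
        name=model.name,
        force_model=model.force_model,
        neutral=NeutralConfig(
            theta_deg=math.degrees(model.neutral_state.theta),
            p=tuple(model.neutral_state.p),
        ),
        ligaments=[
            LigamentConfig(
                name=l.name,
                a=tuple(l.a),
                b_local=tuple(l.b_local),
                l_slack=l.l_slack,
                A=l.A,
                B=l.B,
            )
            for l in model.ligaments
        ],
        contacts=[
            ContactConfig(
                O_a=tuple(c.O_a),
                O_b_local=tuple(c.O_b_local),
                r_a=c.r_a,
                r_b=c.r_b,
                E=c.E,
                nu=c.nu,
                multiplicity=c.multiplicity,
            )
            for c in model.contacts
        ],
        solver=SolverConfig(
            tolerance=model.solver.tolerance,
            residual_norm=model.solver.residual_norm,
            max_nfev=model.solver.max_nfev,
            retries=model.solver.retries,
            jitter_theta=model.solver.jitter_theta,
            jitter_p=model.solver.jitter_p,
            seed=model.solver.seed,
        ),
        sweep=sweep if sweep is not None else SweepConfig(),
    )


def load_model(path) -> JointModel:
    """Load and validate a JSON model config; invariant violations raise at
    load time with field-level messages."""
    text = Path(path).read_text()
    return to_joint_model(ModelConfig.loads(text))


def save_model(model: JointModel, path, sweep: SweepConfig | None = None) -> None:
    """Write the model as a deterministic (sorted-keys) JSON config."""
    Path(path).write_text(from_joint_model(model, sweep).dumps())


def models_equal(m1: JointModel, m2: JointModel) -> bool:
    """Structural equality via the canonical serialized form."""
    return from_joint_model(m1).dumps() == from_joint_model(m2).dumps()
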
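"""Shared fixtures and toy-model builders."""

import numpy as np
import pytest

from plankle import JointState, Ligament2D
from plankle.contacts import ContactPair
from plankle.fixtures import FixtureSpec, default_ankle_fixture
from plankle.statics import JointModel, SolverSettings


@pytest.fixture(scope="session")
def ankle():
    """The default synthetic ankle model (printed force law)."""
    return default_ankle_fixture()


@pytest.fixture(scope="session")
def ankle_continuous():
    """Default geometry with the continuous exponential law."""
    return default_ankle_fixture(FixtureSpec(force_model="exp_minus_one"))


def toy_1dof_model(A=1.0, B=4.0, L=20.0, h=5.0, force_model="exp_shifted"):
    """Two pairs of collinear opposing cables along x at heights +/-h.

    By symmetry rotation and y-translation are blocked, leaving a scalar
    balance in px that a bisection solve can check independently.
    """
    ligaments = []
    for side, ax in (("left", -L), ("right", L)):
        for hh in (h, -h):
            ligaments.append(
                Ligament2D(
                    name=f"{side}_{'up' if hh > 0 else 'dn'}",
                    a=np.array([ax, hh]),
                    b_local=np.array([0.0, hh]),
                    l_slack=L,
                    A=A,
                    B=B,
                )
            )
    return JointModel(
        ligaments=ligaments,
        contacts=[],
        force_model=force_model,
        name="collinear 1-dof toy",
        neutral_state=JointState(0.0, np.zeros(2)),
        solver=SolverSettings(),
    )


def mirror_symmetric_model(force_model="exp_shifted"):
    """A model symmetric under x -> -x: two mirrored vertical cables plus a
    centered contact.  Moment sweeps on it must give antisymmetric rotation."""
    r_a, r_b = 22.0, 20.0
    p0 = np.array([0.0, r_a - r_b])
    ligaments = []
    for sx in (-1.0, 1.0):
        a = np.array([12.0 * sx, 16.0])
        b_neutral = np.array([12.0 * sx, -8.0])
        ligaments.append(
            Ligament2D(
                name=f"cable_{'l' if sx < 0 else 'r'}",
                a=a,
                b_local=b_neutral - p0,
                l_slack=float(np.linalg.norm(b_neutral - a)),
                A=1.0,
                B=20.0,
            )
        )
    contact = ContactPair(
        O_a=np.zeros(2), O_b_local=np.zeros(2), r_a=r_a, r_b=r_b,
        E=10.0, nu=0.46, multiplicity=2,
    )
    return JointModel(
        ligaments=ligaments,
        contacts=[contact],
        force_model=force_model,
        name="mirror-symmetric toy",
        neutral_state=JointState(0.0, p0),
        solver=SolverSettings(),
    )
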
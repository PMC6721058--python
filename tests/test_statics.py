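"""Equilibrium residual, solver, and moment sweeps."""

import numpy as np
import pytest
from scipy.optimize import brentq

from plankle import (
    JointState,
    Ligament2D,
    LoadCase,
    residual,
    residual_norm_value,
    rotation_matrix,
    solve_equilibrium,
    sweep_moments,
    total_elastic_potential,
    total_potential,
)
from plankle.ligaments import force_magnitude, ligament_force
from plankle.statics import JointModel, SolverSettings, _RawState

from conftest import mirror_symmetric_model, toy_1dof_model


class TestResidual:
    def test_unloaded_neutral_of_default_fixture_balances_exactly(self, ankle):
        r = residual(ankle.neutral_state, ankle, LoadCase.pure_moment(0.0))
        assert np.all(r == 0.0)

    def test_constructed_balance_single_active_cable(self):
        """A load chosen as the exact negative of one taut cable's force and
        moment zeroes the residual."""
        lig = Ligament2D("only", np.array([0.0, 10.0]), np.zeros(2), 5.0, 2.0, 3.0)
        model = JointModel(ligaments=[lig], contacts=[])
        state = JointState(0.0, np.array([0.0, 2.0]))  # length 8, strain 0.6
        load_of_cable = ligament_force(lig, state)
        assert load_of_cable.active
        lc = LoadCase(-load_of_cable.force_vector, -load_of_cable.moment / 1000.0)
        assert np.allclose(residual(state, model, lc), 0.0, atol=1e-15)

    def test_residual_equals_negative_energy_gradient_plus_load(self, ankle):
        """Central finite differences of the elastic potential along the
        three rigid-body motions (rotation about the basis origin, x and y
        translations) reproduce the residual to <= 1e-5 relative error."""
        rng = np.random.default_rng(99)
        load = LoadCase(np.array([4.0, -6.0]), 0.8)
        h = 1e-6
        for _ in range(200):
            th = rng.uniform(-0.45, 0.45)
            p = ankle.neutral_state.p + rng.uniform(-2.0, 2.0, 2)
            r = residual(_RawState(th, p), ankle, load)

            def U(t, q):
                return total_elastic_potential(ankle, _RawState(t, q))

            dU_rot = (
                U(th + h, rotation_matrix(h) @ p) - U(th - h, rotation_matrix(-h) @ p)
            ) / (2 * h)
            dU_x = (U(th, p + [h, 0.0]) - U(th, p - [h, 0.0])) / (2 * h)
            dU_y = (U(th, p + [0.0, h]) - U(th, p - [0.0, h])) / (2 * h)
            oracle = np.array(
                [
                    -dU_x + load.F_ext[0],
                    -dU_y + load.F_ext[1],
                    (-dU_rot + load.M_ext_nmm) / 1000.0,
                ]
            )
            err = np.linalg.norm(r - oracle) / max(np.linalg.norm(oracle), 1e-9)
            assert err <= 1e-5

    def test_norm_conventions(self):
        r = np.array([1.0, -2.0, 2.0])
        assert residual_norm_value(r, "sum_abs") == pytest.approx(5.0)
        assert residual_norm_value(r, "l2") == pytest.approx(3.0)
        with pytest.raises(ValueError):
            residual_norm_value(r, "linf")


class TestSolve:
    def test_unloaded_solve_returns_neutral(self, ankle):
        res = solve_equilibrium(ankle, LoadCase.pure_moment(0.0))
        assert res.converged
        assert res.residual_norm < 1e-10
        assert abs(res.state.theta) < 1e-12
        assert np.allclose(res.state.p, ankle.neutral_state.p, atol=1e-12)

    def test_1dof_toy_matches_bisection_oracle(self):
        """Axial force on the collinear toy: px must match a scalar bisection
        solve of 2*A*exp(B*px/L - 1) = F_ext to <= 1e-9 mm."""
        A, B, L = 1.0, 4.0, 20.0
        model = toy_1dof_model(A=A, B=B, L=L)
        F = 30.0
        res = solve_equilibrium(model, LoadCase(np.array([F, 0.0]), 0.0))
        assert res.converged

        def scalar_balance(px):
            return F - 2.0 * force_magnitude(A, B, px / L)

        px_oracle = brentq(scalar_balance, 1e-9, 3 * L, xtol=1e-13, rtol=1e-15)
        assert res.state.p[0] == pytest.approx(px_oracle, abs=1e-9)
        assert res.state.p[1] == pytest.approx(0.0, abs=1e-9)
        assert res.state.theta == pytest.approx(0.0, abs=1e-10)

    def test_converged_solve_is_local_energy_minimum(self, ankle):
        """The equilibrium under a pure moment minimizes Pi = U - M*theta
        against random small perturbations."""
        rng = np.random.default_rng(5)
        for m in (0.6, -1.4):
            lc = LoadCase.pure_moment(m)
            res = solve_equilibrium(ankle, lc)
            assert res.converged
            Pi0 = total_potential(ankle, res.state, lc)
            for _ in range(100):
                d = rng.uniform(-1e-3, 1e-3, 3)
                st = _RawState(res.state.theta + d[0], res.state.p + d[1:])
                assert total_potential(ankle, st, lc) >= Pi0 - 1e-9

    def test_model_without_elements_is_rejected(self):
        model = JointModel(ligaments=[], contacts=[])
        with pytest.raises(ValueError):
            solve_equilibrium(model, LoadCase.pure_moment(0.1))

    def test_nonconvergence_is_flagged_not_silent(self, ankle):
        """A moment inside the near-neutral activation gap of the printed
        law has no exact equilibrium; the solver must say so."""
        res = solve_equilibrium(ankle, LoadCase.pure_moment(-0.003))
        assert not res.converged
        assert res.residual_norm >= ankle.solver.tolerance


class TestSweep:
    def test_zero_only_grid_stays_neutral(self, ankle):
        table = sweep_moments(ankle, [0.0])
        df = table.to_dataframe()
        assert len(df) == 1
        assert df.loc[0, "dtheta_deg"] == pytest.approx(0.0, abs=1e-12)

    def test_mirror_symmetric_model_rotates_antisymmetrically(self):
        model = mirror_symmetric_model()
        grid = np.array([-0.5, -0.25, 0.0, 0.25, 0.5])
        df = sweep_moments(model, grid).to_dataframe()
        assert df["converged"].all()
        for m in (0.25, 0.5):
            plus = df.loc[np.isclose(df.m_ext_nm, m), "dtheta_deg"].iloc[0]
            minus = df.loc[np.isclose(df.m_ext_nm, -m), "dtheta_deg"].iloc[0]
            assert plus == pytest.approx(-minus, abs=1e-8)

    def test_warm_and_cold_starts_reach_identical_equilibria(self, ankle):
        grid = np.linspace(-5.0, 5.0, 21)
        warm = sweep_moments(ankle, grid, warm_start=True).to_dataframe()
        cold = sweep_moments(ankle, grid, warm_start=False).to_dataframe()
        assert warm["converged"].all() and cold["converged"].all()
        for col in ("dtheta_deg", "px_mm", "py_mm"):
            assert np.max(np.abs(warm[col].values - cold[col].values)) <= 1e-8

    def test_rotation_magnitude_monotone_in_moment_magnitude(self, ankle):
        df = sweep_moments(ankle, np.linspace(-5, 5, 51)).to_dataframe()
        assert df["converged"].all()
        pos = df.loc[df.m_ext_nm >= 0, "dtheta_deg"].abs().values
        neg = df.loc[df.m_ext_nm <= 0, "dtheta_deg"].abs().values[::-1]
        assert np.all(np.diff(pos) >= -1e-9)
        assert np.all(np.diff(neg) >= -1e-9)

    def test_angular_stiffness_ramps_up(self, ankle):
        """Secant stiffness |M/dtheta| at 5 N*m exceeds that at 0.2 N*m in
        both directions."""
        df = sweep_moments(ankle, np.linspace(-5, 5, 51)).to_dataframe()
        for sign in (1.0, -1.0):
            th5 = df.loc[np.isclose(df.m_ext_nm, 5 * sign), "dtheta_deg"].iloc[0]
            th02 = df.loc[np.isclose(df.m_ext_nm, 0.2 * sign), "dtheta_deg"].iloc[0]
            assert abs(5.0 / th5) > abs(0.2 / th02)

    def test_csv_table_layout(self, ankle, tmp_path):
        table = sweep_moments(ankle, [0.0, 0.4, -0.4])
        df = table.to_dataframe()
        n = ankle.n_ligaments
        assert df.shape[1] == 4 + 2 * n + 2
        expected_head = ["m_ext_nm", "dtheta_deg", "px_mm", "py_mm"]
        assert list(df.columns[:4]) == expected_head
        assert list(df.columns[-2:]) == ["force_contact_n", "converged"]
        out = tmp_path / "sweep.csv"
        table.to_csv(out)
        header = out.read_text().splitlines()[0].split(",")
        assert header == list(df.columns)
        assert list(df["m_ext_nm"]) == sorted(df["m_ext_nm"])

    def test_partial_flag_on_infeasible_step(self, ankle):
        """Grid points inside the printed law's activation gap abort their
        branch and flag the table."""
        table = sweep_moments(ankle, [-0.003, 0.0])
        assert table.partial
        df = table.to_dataframe()
        assert not df.loc[np.isclose(df.m_ext_nm, -0.003), "converged"].iloc[0]

    def test_converged_steps_satisfy_acceptance_tolerance(self, ankle):
        table = sweep_moments(ankle, np.linspace(-5, 5, 11))
        for res in table.results:
            assert res.converged
            assert residual_norm_value(res.residual, "sum_abs") < 1e-10


def test_solver_settings_validation():
    with pytest.raises(ValueError):
        SolverSettings(residual_norm="max")
    with pytest.raises(ValueError):
        SolverSettings(tolerance=0.0)
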
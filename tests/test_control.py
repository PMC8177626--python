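"""Cost evaluation, QP optimality, duration search, force quadratic."""

import numpy as np
import pytest

from eyeplant import kinematics as kin
from eyeplant.control import (
    CostWeights,
    SaccadePlanner,
    calibrate_weights,
    estimate_force_hessian,
    evaluate_costs,
)
from eyeplant.plant import PlantConfig
from eyeplant.sysid import simulate_linear


def aed():
    return CostWeights.preset("AED")


class TestCostWeights:
    def test_unknown_functional_rejected(self):
        with pytest.raises(ValueError):
            CostWeights("ADE")

    @pytest.mark.parametrize(
        "name,zero_terms",
        [
            ("AD", ["lambda_e", "lambda_lp1", "lambda_lp2", "lambda_f"]),
            ("AE", ["lambda_d", "lambda_lp1", "lambda_lp2", "lambda_f"]),
            ("AED", ["lambda_lp1", "lambda_lp2", "lambda_f"]),
            ("AEDL1", ["lambda_lp2", "lambda_f"]),
            ("AEDL2", ["lambda_lp1", "lambda_f"]),
            ("Force", ["lambda_lp1", "lambda_lp2"]),
        ],
    )
    def test_presets_zero_absent_terms(self, name, zero_terms):
        w = CostWeights.preset(name)
        for term in zero_terms:
            assert getattr(w, term) == 0.0
        assert w.lambda_a > 0


class TestEvaluateCosts:
    def test_on_target_endpoint_costs_nothing(self):
        R = np.zeros((6, 3))
        R[5, 1:] = [0.1, 0.2]
        c = evaluate_costs(R, np.zeros((6, 3)), 5, aed(), target_yz=[0.1, 0.2])
        assert c["J_A"] == 0.0

    def test_constant_input_at_hold_costs_no_energy(self):
        U = np.tile([0.1, -0.2, 0.3], (6, 1))
        c = evaluate_costs(
            np.zeros((6, 3)), U, 5, aed(), u_hold=np.array([0.1, -0.2, 0.3])
        )
        assert c["J_E"] == 0.0

    def test_literal_convention_charges_first_input(self):
        U = np.tile([0.1, 0.0, 0.0], (6, 1))
        c = evaluate_costs(
            np.zeros((6, 3)), U, 5, aed(), literal_first_difference=True
        )
        assert np.isclose(c["J_E"], 0.01)

    def test_duration_discount_limits(self):
        w = aed()
        zero = evaluate_costs(np.zeros((3, 3)), np.zeros((3, 3)), 0, w)
        assert zero["J_D"] == 0.0
        n = 2001
        long = evaluate_costs(np.zeros((n, 3)), np.zeros((n, 3)), n - 1, w)
        assert long["J_D"] == pytest.approx(1.0, abs=0.01)
        assert long["J_D"] < 1.0  # approaches but never reaches the limit

    def test_zero_torsion_trajectory_has_zero_listing_costs(self):
        R = np.random.default_rng(0).normal(size=(6, 3))
        R[:, 0] = 0.0
        c = evaluate_costs(R, np.zeros((6, 3)), 5, aed())
        assert c["J_LP1"] == 0.0 and c["J_LP2"] == 0.0


class TestForceQuadratic:
    def test_symmetric_psd(self, force_quadratic):
        H = force_quadratic.H
        assert np.allclose(H, H.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(H) >= -1e-12)

    def test_minimizer_torsion_near_zero_and_valley_is_flat(self, force_quadratic, plant):
        """The total tension is nearly conserved along gaze direction
        (antagonists trade load), so the quadratic has a flat valley in
        (ry, rz); only the torsional minimizer is sharply defined, and for
        the near-symmetric geometry it sits close to zero torsion."""
        from eyeplant.plant import total_tension
        from eyeplant import kinematics as kin

        m_deg = np.degrees(2 * np.arctan(force_quadratic.minimizer))
        assert abs(m_deg[0]) < 3.0
        # flat valley: tension at the fitted minimizer is within 2% of rest
        t_min = total_tension(
            kin.rotvec_to_quat(force_quadratic.minimizer), np.zeros(3), plant
        )
        t_rest = total_tension(kin.qidentity(), np.zeros(3), plant)
        assert abs(t_min - t_rest) < 0.02 * t_rest

    def test_shifted_plant_tilts_the_quadratic(self, force_quadratic):
        """The torsion/horizontal cross-curvature moves monotonically with a
        vertical shift of the cranial insertions."""
        cfg8 = PlantConfig.table1().with_dz(8.0)
        fq8 = estimate_force_hessian(cfg8, 5, 30.0)
        b0 = -force_quadratic.H[0, 2] / force_quadratic.H[0, 0]
        b8 = -fq8.H[0, 2] / fq8.H[0, 0]
        assert abs(b8) > abs(b0) + 0.05
        assert np.sign(b8) != 0


class TestSolveFixedDuration:
    def test_zero_displacement_costs_only_duration(self, model):
        w = aed()
        pl = SaccadePlanner(model, w)
        x0, u_hold = model.steady_state(np.array([0.0, 0.1, 0.1]))
        U, costs = pl.solve_fixed_duration(10, x0, np.array([0.1, 0.1]), u_hold)
        assert costs["J_E"] < 1e-8
        assert np.allclose(U, u_hold, atol=1e-4)
        assert costs["J_TOT"] == pytest.approx(
            w.lambda_d * costs["J_D"], rel=1e-4
        )

    def test_constraint_mode_hits_endpoint_exactly(self, model):
        pl = SaccadePlanner(model, aed(), mode="constraint")
        x0, u_hold = model.steady_state(np.zeros(3))
        tgt = kin.deg_components_to_rotvec([5.0, 10.0])
        U, _ = pl.solve_fixed_duration(15, x0, tgt, u_hold)
        R = simulate_linear(model, U, x0)
        assert np.abs(R[-1, 1:] - tgt).max() < 1e-6

    def test_penalty_and_constraint_modes_agree(self, model):
        x0, u_hold = model.steady_state(np.zeros(3))
        tgt = kin.deg_components_to_rotvec([0.0, 15.0])
        U_p, _ = SaccadePlanner(model, aed(), mode="penalty").solve_fixed_duration(
            15, x0, tgt, u_hold
        )
        U_c, _ = SaccadePlanner(model, aed(), mode="constraint").solve_fixed_duration(
            15, x0, tgt, u_hold
        )
        end_p = simulate_linear(model, U_p, x0)[-1]
        end_c = simulate_linear(model, U_c, x0)[-1]
        assert np.degrees(2 * np.abs(end_p - end_c)).max() < 0.1

    def test_cost_matches_independent_rollout(self, model):
        """Dual route: the planner's internal rollout vs simulate_linear."""
        pl = SaccadePlanner(model, aed())
        x0, u_hold = model.steady_state(np.zeros(3))
        tgt = kin.deg_components_to_rotvec([5.0, -10.0])
        U, costs = pl.solve_fixed_duration(12, x0, tgt, u_hold)
        R = simulate_linear(model, U, x0)
        again = evaluate_costs(R, U, 12, aed(), target_yz=tgt, u_hold=u_hold)
        assert again["J_TOT"] == pytest.approx(costs["J_TOT"], rel=1e-8, abs=1e-12)

    def test_relaxing_a_weight_cannot_increase_cost(self, model):
        x0, u_hold = model.steady_state(np.zeros(3))
        tgt = kin.deg_components_to_rotvec([0.0, 12.0])
        w_full = CostWeights("AEDL1", lambda_e=1.0, lambda_d=5.0, lambda_lp1=100.0)
        _, c_full = SaccadePlanner(model, w_full).solve_fixed_duration(
            15, x0, tgt, u_hold
        )
        w_rel = CostWeights("AEDL1", lambda_e=1.0, lambda_d=5.0, lambda_lp1=0.0)
        _, c_rel = SaccadePlanner(model, w_rel).solve_fixed_duration(
            15, x0, tgt, u_hold
        )
        # compare both solutions under the relaxed objective
        full_under_rel = (
            c_full["J_TOT"] - w_full.lambda_lp1 * c_full["J_LP1"]
        )
        assert c_rel["J_TOT"] <= full_under_rel + 1e-9

    def test_kkt_stationarity(self, model):
        """Gradient of the penalized objective vanishes at the solution."""
        pl = SaccadePlanner(model, aed())
        x0, u_hold = model.steady_state(np.zeros(3))
        tgt = kin.deg_components_to_rotvec([0.0, 10.0])
        D = 12
        U, _ = pl.solve_fixed_duration(D, x0, tgt, u_hold)
        c = pl._caches[D]
        # rebuild the linear term exactly as the solver does
        g = np.zeros(c.n_var)
        e0 = np.zeros(c.n_var)
        e0[:3] = u_hold
        g -= (pl.weights.lambda_e + 1e-8) * (c.Delta.T @ e0)
        fa = c.F[3 * D + 1 : 3 * D + 3] @ x0 - tgt
        g += pl.weights.lambda_a * (c.KA.T @ fa)
        m1 = (np.eye(6) - model.A) @ (c.AD @ x0)
        g_pen = g + pl.penalty * (c.KA.T @ fa) + pl.penalty * (c.M1.T @ m1)
        grad = 2 * c.H @ U.reshape(-1) + 2 * g_pen
        assert np.abs(grad).max() < 1e-6 * (1 + np.abs(2 * c.H).max())


class TestPlanSaccade:
    def test_ten_degree_curve_is_u_shaped(self, model, plant):
        sol = SaccadePlanner(model, aed(), plant=plant).plan(
            np.zeros(3), kin.deg_components_to_rotvec([0.0, 10.0])
        )
        assert not sol.boundary
        curve = sol.cost_curve
        k = np.argmin(curve)
        assert 0 < k < len(curve) - 1
        # U shape: decreasing into the minimum (the very shortest durations,
        # where the terminal conditions dominate, are exempt) and
        # increasing after it
        assert np.all(np.diff(curve[1 : k + 1]) <= 1e-12)
        assert np.all(np.diff(curve[k:]) >= -1e-12)

    def test_duration_free_plan_takes_longest_duration(self, model):
        sol = SaccadePlanner(model, CostWeights.preset("AE")).plan(
            np.zeros(3), kin.deg_components_to_rotvec([0.0, 10.0])
        )
        assert sol.D == 40

    def test_duration_nondecreasing_in_amplitude(self, model):
        pl = SaccadePlanner(model, aed())
        ds = [
            pl.plan(np.zeros(3), kin.deg_components_to_rotvec([0.0, a])).D
            for a in [2, 5, 10, 20, 30, 40]
        ]
        assert all(b >= a for a, b in zip(ds, ds[1:]))

    def test_peak_velocity_saturates_under_aed(self, model, plant):
        pl = SaccadePlanner(model, aed(), plant=plant)

        def vpk(a):
            sol = pl.plan(np.zeros(3), kin.deg_components_to_rotvec([0.0, a]))
            return np.degrees(np.linalg.norm(sol.trajectory.omega, axis=1)).max()

        assert vpk(40.0) / vpk(10.0) < 4.0

    def test_force_functional_requires_quadratic(self, model):
        with pytest.raises(ValueError):
            SaccadePlanner(model, CostWeights.preset("Force"))


def test_calibration_places_interior_optimum(model):
    w = calibrate_weights(model, d_target_ticks=13)
    assert w["lambda_d"] > 0
    planner = SaccadePlanner(
        model, CostWeights("AED", lambda_e=w["lambda_e"], lambda_d=w["lambda_d"],
                           beta=w["beta"])
    )
    sol = planner.plan(np.zeros(3), kin.deg_components_to_rotvec([0.0, 10.0]))
    assert abs(sol.D - 13) <= 1
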
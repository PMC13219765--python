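"""Weighted static optimization: closed forms, oracle equivalence, KKT
properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solband.errors import ParameterError
from solband.model import FrameGeometry
from solband.solver import (SolverOptions, WeightVector, solve_frame,
                            solve_trial, solve_trial_emg_constrained)

from helpers import constant_trial, one_dof_model, simple_geometry
from oracles import qp_box_oracle


def two_muscle_frame(torque=50.0, f_max=(1000.0, 1000.0), arm=0.05):
    model = one_dof_model(f_max=f_max)
    geo = simple_geometry(model, [[arm, arm]])
    return model, geo, np.array([torque])


class TestSolveFrame:
    def test_identical_muscles_split_equally(self):
        model, geo, tau = two_muscle_frame()
        sol = solve_frame(geo, tau, model, WeightVector.ones(2))
        np.testing.assert_allclose(sol.activations, [0.5, 0.5], atol=1e-8)
        assert sol.converged
        assert abs(sol.cost - 0.5) < 1e-8

    def test_asymmetric_weights_closed_form(self):
        # KKT on a1 + a2 = 1 with cost a1^2 + 100 a2^2: a = (100, 1)/101
        model, geo, tau = two_muscle_frame()
        wv = WeightVector(np.array([1.0, 100.0]))
        sol = solve_frame(geo, tau, model, wv)
        np.testing.assert_allclose(sol.activations, [100 / 101, 1 / 101],
                                   atol=1e-8)

    def test_zero_torque_zero_activation(self):
        model, geo, _ = two_muscle_frame()
        sol = solve_frame(geo, np.array([0.0]), model,
                          WeightVector(np.array([1.0, 100.0])))
        np.testing.assert_allclose(sol.activations, 0.0, atol=1e-9)
        assert sol.cost == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_frame_raises_with_worst_dof(self):
        # torque beyond total muscle capacity: 2 * 0.05 * 1000 = 100 N m max
        model, geo, _ = two_muscle_frame()
        from solband.errors import InfeasibleFrameError
        with pytest.raises(InfeasibleFrameError) as err:
            solve_frame(geo, np.array([150.0]), model, WeightVector.ones(2))
        assert err.value.worst_dof == "flexion"
        sol = solve_frame(geo, np.array([150.0]), model, WeightVector.ones(2),
                          raise_infeasible=False)
        assert not sol.converged

    def test_reserves_rescue_infeasible_frame(self):
        model, geo, _ = two_muscle_frame()
        sol = solve_frame(geo, np.array([150.0]), model, WeightVector.ones(2),
                          SolverOptions(reserve_enabled=True))
        assert sol.converged and sol.used_reserves
        assert abs(sol.reserves[0] - 50.0) < 1e-3  # slack picks up the rest


class TestSolveTrial:
    def test_zero_torques(self):
        model = one_dof_model()
        trial = constant_trial(model, [0.0], n_frames=3)
        sol = solve_trial(trial, model, WeightVector.ones(2))
        np.testing.assert_allclose(sol.activations, 0.0, atol=1e-9)

    def test_constant_torque_constant_solution(self):
        model = one_dof_model()
        trial = constant_trial(model, [50.0], n_frames=4)
        sol = solve_trial(trial, model, WeightVector.ones(2))
        for k in range(1, 4):
            np.testing.assert_allclose(sol.activations[k],
                                       sol.activations[0], atol=1e-9)

    def test_ramp_torque_linear_activation(self):
        model = one_dof_model()
        n = 11
        trial = constant_trial(model, [0.0], n_frames=n)
        trial.torques = np.linspace(0, 50, n)[:, None]
        sol = solve_trial(trial, model, WeightVector.ones(2))
        np.testing.assert_allclose(sol.activations[:, 0],
                                   np.linspace(0, 0.5, n), atol=1e-7)

    def test_muscle_forces_are_activation_times_fmax(self):
        model = one_dof_model(f_max=(800.0, 1200.0))
        trial = constant_trial(model, [40.0], n_frames=3)
        sol = solve_trial(trial, model, WeightVector.ones(2))
        np.testing.assert_allclose(
            sol.muscle_forces, sol.activations * model.f_max, atol=1e-12)


class TestEmgConstrained:
    def test_vacuous_delta_matches_unconstrained(self):
        model = one_dof_model(emg_measured=(True, True))
        trial = constant_trial(model, [50.0], n_frames=3)
        trial.emg = np.full((3, 2), 0.9)
        free = solve_trial(trial, model, WeightVector.ones(2))
        boxed = solve_trial_emg_constrained(
            trial, model, WeightVector.ones(2), SolverOptions(emg_tolerance=1.0))
        np.testing.assert_allclose(boxed.activations, free.activations,
                                   atol=1e-8)

    def test_tracking_box_binds(self):
        # a1 + a2 = 1, minimize a1^2 + a2^2 with a1 in [0.25, 0.35]:
        # boundary optimum at a1 = 0.35
        model = one_dof_model(emg_measured=(True, False))
        trial = constant_trial(model, [50.0], n_frames=3)
        trial.emg = np.full((3, 1), 0.3)
        sol = solve_trial_emg_constrained(
            trial, model, WeightVector.ones(2), SolverOptions(emg_tolerance=0.05))
        np.testing.assert_allclose(sol.activations[0], [0.35, 0.65], atol=1e-8)

    def test_constrained_cost_never_below_unconstrained(self):
        model = one_dof_model(emg_measured=(True, False))
        trial = constant_trial(model, [50.0], n_frames=3)
        trial.emg = np.full((3, 1), 0.1)
        free = solve_trial(trial, model, WeightVector.ones(2))
        boxed = solve_trial_emg_constrained(trial, model, WeightVector.ones(2))
        assert boxed.total_cost >= free.total_cost - 1e-9

    def test_truth_pinned_by_tight_box(self, model12, clean_trial):
        trial, truth = clean_trial
        sol = solve_trial_emg_constrained(
            trial, model12, WeightVector.ones(model12.m),
            SolverOptions(emg_tolerance=0.01))
        s, e = sol.frame_window
        meas = list(model12.emg_measured_indices)
        err = np.abs(sol.activations[:, meas]
                     - truth.activations[s:e + 1, meas])
        assert err.max() <= 0.01 + 1e-6


class TestSolverProperties:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_weight_scaling_invariance(self, seed):
        """Multiplying all weights by a constant leaves activations alone."""
        rng = np.random.default_rng(seed)
        model, geo, _ = two_muscle_frame(f_max=(900.0, 1400.0))
        tau = np.array([rng.uniform(5, 80)])
        w = rng.choice([1.0, 10.0, 100.0], 2)
        s1 = solve_frame(geo, tau, model, WeightVector(w))
        s2 = solve_frame(geo, tau, model, WeightVector(7 * w))
        np.testing.assert_allclose(s1.activations, s2.activations, atol=1e-6)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_raising_a_weight_never_raises_its_activation(self, seed):
        rng = np.random.default_rng(seed)
        model, geo, _ = two_muscle_frame()
        tau = np.array([rng.uniform(5, 90)])
        lo = solve_frame(geo, tau, model, WeightVector(np.array([1.0, 1.0])))
        hi = solve_frame(geo, tau, model, WeightVector(np.array([100.0, 1.0])))
        assert hi.activations[0] <= lo.activations[0] + 1e-8

    def test_equilibrium_residuals(self, model12, noisy_trial):
        trial, _ = noisy_trial
        wv = WeightVector(np.random.default_rng(3).choice(
            model12.weight_levels, model12.m))
        sol = solve_trial(trial, model12, wv)
        s, e = sol.frame_window
        scale = np.maximum(1.0, np.abs(trial.torques[s:e + 1]))
        assert np.all(np.abs(sol.residuals) <= 1e-6 * scale)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_active_set_oracle(self, seed):
        """Random small frames agree with the exhaustive KKT oracle."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 5))
        nd = int(rng.integers(1, 3))
        model = one_dof_model(f_max=tuple(rng.uniform(500, 2000, m)))
        # build arbitrary gain structure directly at QP level
        G = rng.uniform(-0.06, 0.06, (nd, m)) * model.f_max[:m]
        a_feas = rng.uniform(0.05, 0.9, m)
        tau = G @ a_feas
        w = rng.choice([1.0, 10.0, 100.0], m)
        from solband.solver import _solve_qp_dual
        a, _, _, ok = _solve_qp_dual(G, tau, w, np.zeros(m), np.ones(m),
                                     1e-8 * np.maximum(1, np.abs(tau)))
        ref = qp_box_oracle(G, tau, w)
        assert ok and ref is not None
        assert np.max(np.abs(a - ref)) <= 1e-3
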
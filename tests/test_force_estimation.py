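"""Inverse dynamics: objective, per-step estimation, trial-level recovery."""

import numpy as np
import pytest

from trunksim.dynamics import SystemState, TrunkDynamics
from trunksim.force_estimation import (ActiveForceHistory, ForceUnknowns,
                                       estimate_step_forces,
                                       map_unknowns_to_rod_forces, run_inverse,
                                       segment_force_summary,
                                       tracked_dof_indices, tracking_objective)
from trunksim.synthetic_data import generate_ground_truth_forces


@pytest.fixture(scope="module")
def toy_dyn(toy_structure):
    return TrunkDynamics(toy_structure)


class TestForceUnknowns:
    def test_vector_round_trip(self):
        u = ForceUnknowns([1.0, 2.0], [3.0, 4.0], [5.0, 6.0])
        back = ForceUnknowns.from_vector(u.to_vector(), 2)
        assert np.array_equal(back.fl_dorsal, u.fl_dorsal)
        assert np.array_equal(back.fr, u.fr)

    def test_rod_force_mapping(self, toy_structure):
        u = ForceUnknowns([10.0, 0.0], [4.0, 0.0], [8.0, 0.0])
        f = map_unknowns_to_rod_forces(toy_structure, u)
        assert f[toy_structure.rod_id("longitudinal", 1, "P")] == 10.0
        assert f[toy_structure.rod_id("longitudinal", 1, "Q")] == 4.0
        # mirrored lateral columns carry the segment's mean drive Fm_L = 7
        assert f[toy_structure.rod_id("longitudinal", 1, "B")] == 7.0
        assert f[toy_structure.rod_id("longitudinal", 1, "A")] == 7.0
        radial = [f[toy_structure.rod_id("radial", 2, r)]
                  for r in ("P", "B", "Q", "A")]
        assert np.allclose(radial, 2.0)
        assert f.sum() == pytest.approx(10 + 4 + 2 * 7 + 8)

    def test_rod_force_mapping_passive_laterals(self, toy_structure):
        u = ForceUnknowns([10.0, 0.0], [4.0, 0.0], [8.0, 0.0])
        f = map_unknowns_to_rod_forces(toy_structure, u, lateral_mode="passive")
        assert f[toy_structure.rod_id("longitudinal", 1, "B")] == 0.0
        assert f.sum() == pytest.approx(10 + 4 + 8)


class TestSegmentForceSummary:
    def test_algebra(self):
        h = ActiveForceHistory(times=np.array([0.0]),
                               fl_dorsal=np.array([[10.0]]),
                               fl_ventral=np.array([[4.0]]),
                               fr=np.array([[7.5]]))
        fr, dfl, fml = segment_force_summary(h)
        assert dfl[0, 0] == 6.0
        assert fml[0, 0] == 7.0
        assert fr[0, 0] == 7.5

    def test_equal_longitudinals_no_bending_drive(self):
        h = ActiveForceHistory(times=np.array([0.0]),
                               fl_dorsal=np.array([[5.0]]),
                               fl_ventral=np.array([[5.0]]),
                               fr=np.array([[1.0]]))
        _, dfl, fml = segment_force_summary(h)
        assert dfl[0, 0] == 0.0
        assert fml[0, 0] == 5.0

    def test_round_trip_reconstruction(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=(5, 3))
        v = rng.normal(size=(5, 3))
        h = ActiveForceHistory(times=np.arange(5.0), fl_dorsal=d, fl_ventral=v,
                               fr=np.zeros((5, 3)))
        _, dfl, fml = segment_force_summary(h)
        assert np.allclose(fml + dfl / 2.0, d)
        assert np.allclose(fml - dfl / 2.0, v)


class TestTrackingObjective:
    def test_zero_for_models_own_passive_step(self, toy_structure, toy_dyn):
        state = toy_dyn.rest_state()
        passive = toy_dyn.step(state, np.zeros(toy_structure.n_rods), 0.02)
        target = passive.q - state.q
        obj = tracking_objective(ForceUnknowns.zeros(2), toy_dyn, state,
                                 target, 0.02)
        assert obj == pytest.approx(0.0, abs=1e-12)

    def test_zero_at_generating_forces(self, toy_structure, toy_dyn):
        truth = ForceUnknowns([12.0, -5.0], [3.0, 8.0], [6.0, 2.0])
        f = map_unknowns_to_rod_forces(toy_structure, truth)
        state = toy_dyn.rest_state()
        end = toy_dyn.step(state, f, 0.02)
        obj = tracking_objective(truth, toy_dyn, state, end.q - state.q, 0.02,
                                 tracked=tracked_dof_indices(toy_structure, "all"))
        assert obj < 1e-10

    def test_non_negative(self, toy_structure, toy_dyn):
        rng = np.random.default_rng(5)
        for _ in range(3):
            u = ForceUnknowns(*rng.normal(0, 10, (3, 2)))
            target = rng.normal(0, 1e-3, toy_structure.n_dof)
            assert tracking_objective(u, toy_dyn, toy_dyn.rest_state(),
                                      target, 0.02) >= 0.0

    def test_invalid_dt(self, toy_dyn, toy_structure):
        with pytest.raises(ValueError):
            tracking_objective(ForceUnknowns.zeros(2), toy_dyn,
                               toy_dyn.rest_state(),
                               np.zeros(toy_structure.n_dof), 0.0)


class TestEstimateStepForces:
    def test_recovers_known_step_forces(self, toy_structure, toy_dyn):
        truth = ForceUnknowns([15.0, 8.0], [4.0, 10.0], [9.0, 3.0])
        f = map_unknowns_to_rod_forces(toy_structure, truth)
        state = toy_dyn.rest_state()
        end = toy_dyn.step(state, f, 0.02)
        tracked = tracked_dof_indices(toy_structure, "all")
        est, info = estimate_step_forces(toy_dyn, state, end.q - state.q, 0.02,
                                         tracked=tracked)
        assert info["converged"]
        assert np.allclose(est.to_vector(), truth.to_vector(),
                           rtol=0.02, atol=0.2)

    def test_zero_target_from_equilibrium_gives_zero_forces(self, toy_structure):
        dyn = TrunkDynamics(toy_structure, gravity=0.0)
        est, _ = estimate_step_forces(dyn, dyn.rest_state(),
                                      np.zeros(toy_structure.n_dof), 0.02,
                                      tracked=tracked_dof_indices(toy_structure, "all"))
        assert np.abs(est.to_vector()).max() < 1e-3

    def test_objective_not_worse_than_warm_start(self, toy_structure, toy_dyn):
        rng = np.random.default_rng(9)
        target = rng.normal(0, 5e-4, toy_structure.n_dof)
        state = toy_dyn.rest_state()
        tracked = tracked_dof_indices(toy_structure, "all")
        warm = ForceUnknowns.zeros(2)
        est, info = estimate_step_forces(toy_dyn, state, target, 0.02,
                                         warm_start=warm, tracked=tracked)
        obj_warm_start = tracking_objective(warm, toy_dyn, state, target, 0.02,
                                            tracked=tracked)
        assert info["objective"] <= obj_warm_start + 1e-12


class TestRunInverse:
    def test_recovers_smooth_force_history(self, toy_structure, toy_dyn):
        """Forward-generated forces are recovered within 5% RMS."""
        pos, truth = generate_ground_truth_forces(toy_structure, seed=7,
                                                  n_steps=25, dt=0.02,
                                                  amplitude=25.0, dyn=toy_dyn)
        est, sim = run_inverse(pos, toy_structure, dt=0.02,
                               tracked_mode="all", dyn=toy_dyn)
        for name in ("fl_dorsal", "fl_ventral", "fr"):
            t = getattr(truth, name)
            r = getattr(est, name)
            rel_rms = np.sqrt(np.mean((r - t) ** 2)) / np.sqrt(np.mean(t**2))
            assert rel_rms < 0.05, name
        assert est.n_steps == pos.shape[0] - 1

    def test_recovered_fr_correlates_with_truth(self, toy_structure, toy_dyn):
        pos, truth = generate_ground_truth_forces(toy_structure, seed=21,
                                                  n_steps=25, dt=0.02,
                                                  amplitude=25.0, dyn=toy_dyn)
        est, _ = run_inverse(pos, toy_structure, dt=0.02, tracked_mode="all",
                             dyn=toy_dyn)
        for i in range(toy_structure.n_segments):
            c = np.corrcoef(truth.fr[:, i], est.fr[:, i])[0, 1]
            assert c > 0.95

    def test_static_trial_holds_against_gravity(self, toy_structure, toy_dyn):
        """Zero-motion targets from the sagged equilibrium: the estimator
        finds gravity-balancing forces and the simulated tip barely moves."""
        settle = toy_dyn.integrate(toy_dyn.rest_state(), None, (0, 6.0),
                                   t_eval=np.array([6.0]), rtol=1e-8, atol=1e-11)
        eq = settle.states[-1]
        pos_eq = toy_structure.rest_positions() + eq.q.reshape(-1, 3)
        targets = np.repeat(pos_eq[None], 11, axis=0)
        est, sim = run_inverse(targets, toy_structure, dt=0.02,
                               tracked_mode="all", dyn=toy_dyn)
        tip = toy_structure.node_id(toy_structure.n_sections, "O")
        sag = np.linalg.norm(sim[-1, tip] - targets[0, tip])
        assert sag < 1e-3

    def test_history_length(self, toy_structure, toy_dyn):
        pos, _ = generate_ground_truth_forces(toy_structure, seed=3,
                                              n_steps=5, dt=0.02, dyn=toy_dyn)
        est, sim = run_inverse(pos, toy_structure, dt=0.02,
                               tracked_mode="all", dyn=toy_dyn)
        assert est.n_steps == 5
        assert sim.shape == pos.shape

    def test_node_count_mismatch_errors(self, toy_structure):
        with pytest.raises(ValueError):
            run_inverse(np.zeros((3, 7, 3)), toy_structure, dt=0.02)
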
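"""Tests of the forward dynamics, integrator and tracking controller."""

import inspect

import numpy as np
import pytest
from scipy.optimize import root

from afoflex.dynamics_engine import (
    CMCController,
    DynamicsEngine,
    ExternalLoads,
    State,
    StaticBase,
    TrackingTask,
    cmc_step,
    equations_of_motion,
    initial_cmc,
    linear_ramp,
    run_gait_cycle,
)
from afoflex.gait_synth import TrialKinematics, synth_gait, synth_support
from afoflex.interface_model import BushingParams
from afoflex.leg_afo_model import apply_weakening, build_model


def _zero_interface_config(**extra_model):
    zero = BushingParams(np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3)).as_dict()
    cfg = {"interface": {"tibia": zero, "foot": zero}}
    cfg.update(extra_model)
    return cfg


class TestEquationsOfMotion:
    def test_all_forces_zero_gives_zero_acceleration(self, model):
        state = State.neutral(model)
        qdd = equations_of_motion(model, state, ExternalLoads(gravity=False))
        np.testing.assert_allclose(qdd, 0.0, atol=1e-12)

    def test_constant_force_on_auxiliary_assembly_point_mass_oracle(self):
        # closed form: with shell COMs at the device pin the vertical
        # translation decouples and the pin assembly is a point mass
        cfg = _zero_interface_config(
            segments={
                "foot_shell": {"com": [0.0, 0.0, 0.0]},
                "calf_shell": {"com": [0.0, 0.0, 0.0]},
            }
        )
        model = build_model(cfg)
        m_total = (
            model.segments["aux"].mass
            + model.segments["foot_shell"].mass
            + model.segments["calf_shell"].mass
        )
        force = 0.008  # N along +y on the auxiliary translation
        loads = ExternalLoads(
            gravity=False,
            extra_generalized=lambda t: np.array([0, 0, force, 0, 0, 0.0]),
        )
        qdd = equations_of_motion(model, State.neutral(model), loads)
        assert qdd[2] == pytest.approx(force / m_total, rel=1e-12)
        assert np.allclose(np.delete(qdd, 2), 0.0, atol=1e-12)

    def test_singular_mass_matrix_reports_condition(self):
        cfg = {
            "segments": {"foot_shell": {"mass": 1e-09, "inertia_z": 0.0, "com": [0, 0, 0]}}
        }
        model = build_model(cfg)
        with pytest.raises(RuntimeError, match="singular.*condition"):
            equations_of_motion(model, State.neutral(model), ExternalLoads())

    def test_state_validates_activation_bounds(self, model):
        with pytest.raises(ValueError, match="outside"):
            State(np.zeros(6), np.zeros(6), {"plantarflexors": 1.2})


class TestController:
    def _bare_engine(self, model, extra=None):
        loads = ExternalLoads(gravity=False, extra_generalized=extra)
        return DynamicsEngine(model, base=StaticBase(), loads=loads)

    def test_perfect_match_zero_moment_gives_lower_bound_activations(self, model):
        controls, state = cmc_step(
            model,
            State.neutral(model),
            [TrackingTask("ankle_rz", lambda t: 0.0, lambda t: 0.0)],
            dt=1e-3,
            loads=ExternalLoads(gravity=False),
        )
        assert all(a == pytest.approx(0.0, abs=1e-09) for a in controls["activations"].values())

    @pytest.mark.parametrize("m_ext, expected", [(40.0, 0.4), (80.0, 0.8)])
    def test_single_actuator_closed_form(self, m_ext, expected):
        # single-actuator oracle: a = M / (w * f_max * r) for the only
        # muscle able to counter the applied ankle moment
        model = apply_weakening(build_model(_zero_interface_config()), "PF50")
        # PF50: w*f_max*r = 0.5 * 4000 * 0.05 = 100 Nm at full activation
        loads = ExternalLoads(
            gravity=False, extra_generalized=lambda t: np.array([m_ext, 0, 0, 0, 0, 0.0])
        )
        controls, _ = cmc_step(
            model,
            State.neutral(model),
            [TrackingTask("ankle_rz", lambda t: 0.0, lambda t: 0.0, weight=10.0)],
            dt=1e-3,
            loads=loads,
        )
        assert controls["activations"]["plantarflexors"] == pytest.approx(expected, rel=5e-3)
        assert abs(controls["reserves"]["ankle_rz"]) < 0.5

    def test_saturation_flags_reserve_takeover(self):
        model = apply_weakening(build_model(_zero_interface_config()), "PF50")
        loads = ExternalLoads(
            gravity=False, extra_generalized=lambda t: np.array([150.0, 0, 0, 0, 0, 0.0])
        )
        controls, state = cmc_step(
            model,
            State.neutral(model),
            [TrackingTask("ankle_rz", lambda t: 0.0, lambda t: 0.0, weight=10.0)],
            dt=1e-3,
            loads=loads,
        )
        assert controls["activations"]["plantarflexors"] == pytest.approx(1.0)
        assert controls["reserves"]["ankle_rz"] < -10.0  # deficit absorbed, plantarflexion
        assert controls["saturated"] == ["plantarflexors"]
        assert any("saturated" in msg for _, msg in state.flags)

    def test_doubling_task_weight_reduces_its_error(self, model):
        engine = self._bare_engine(model)
        state = State.neutral(model)
        errors = []
        for w in (1.0, 2.0, 4.0):
            tasks = [
                TrackingTask("ankle_rz", lambda t: 0.1, lambda t: 0.0, weight=10.0),
                TrackingTask("footshell_rz", lambda t: -0.1, lambda t: 0.0, weight=w),
            ]
            controller = CMCController(engine, tasks)
            _, diag = controller.solve(state, 0.0)
            errors.append(abs(diag["task_errors"]["footshell_rz"]))
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] < errors[0]


class TestInitialCMC:
    def test_default_number_of_interpolation_steps(self):
        assert inspect.signature(initial_cmc).parameters["n_steps"].default == 10

    def test_linear_ramp_matches_independent_interpolation(self):
        ref, rate = linear_ramp(0.2, -0.3, 10, 0.02)
        knots = np.arange(11) * 0.02
        expected = np.interp(knots, [0.0, 0.2], [0.2, -0.3])
        for k, t in enumerate(knots):
            assert ref(t) == pytest.approx(expected[k], abs=1e-12)
            assert ref(t) == pytest.approx(0.2 + (-0.3 - 0.2) * k / 10, abs=1e-12)
        assert rate(0.1) == pytest.approx((-0.5) / 0.2)
        assert rate(0.5) == 0.0

    def test_identical_poses_settle_to_interface_equilibrium(self, model):
        state = initial_cmc(model)  # default pose == gait pose == neutral
        assert state.flags == ()
        assert abs(state.q[0]) < 2e-3  # tasked coordinate unchanged
        assert np.max(np.abs(state.qdot)) < 2e-3
        # oracle: static equilibrium of the interface springs under gravity
        engine = DynamicsEngine(model, base=StaticBase(), loads=ExternalLoads())
        sol = root(
            lambda x: engine.forces(np.r_[state.q[0], x], np.zeros(6), 0.0)[1:],
            state.q[1:],
            tol=1e-12,
        )
        assert sol.success
        np.testing.assert_allclose(state.q[1:], sol.x, atol=5e-05)

    def test_bootstrap_runs_on_unweakened_model(self, model):
        # a fully paralyzed variant still settles to the same pose because
        # the bootstrap restores full strength internally
        weak = apply_weakening(model, "PF25")
        s_weak = initial_cmc(weak)
        s_full = initial_cmc(model)
        np.testing.assert_allclose(s_weak.q, s_full.q, atol=1e-12)


class TestZeroLoadInvariant:
    def test_static_no_load_markers_identically_zero(self, model):
        engine = DynamicsEngine(
            model, base=StaticBase(), loads=ExternalLoads(gravity=False), dt=1e-3
        )
        controller = CMCController(engine, [TrackingTask("ankle_rz", lambda t: 0.0, lambda t: 0.0)])
        q, v, acts = np.zeros(6), np.zeros(6), {"plantarflexors": 0.0, "dorsiflexors": 0.0}
        t = 0.0
        for _ in range(300):
            st = State(q, v, acts, t)
            controls, _ = controller.solve(st, t, 1e-3)
            acts = controller.advance_activations(st, controls["activations"], 1e-3)
            q, v, _ = engine.step(q, v, t, {"activations": acts, "reserves": controls["reserves"]})
            t += 1e-3
        for disp in engine.marker_displacements(q).values():
            assert np.max(np.abs(disp)) < 1e-12

    def test_moving_gait_no_load_markers_small_versus_loaded(self, model):
        # without gravity and support the only residual relative motion is
        # the shells' inertial response to the accelerating base frame --
        # millimetres, an order of magnitude below the loaded excursions
        trial = synth_gait("slow", 1)
        kin = TrialKinematics(trial, model)
        engine = DynamicsEngine(model, base=kin, loads=ExternalLoads(gravity=False), dt=1e-3)
        controller = CMCController(
            engine,
            [TrackingTask("ankle_rz", kin.theta_ref, kin.theta_ref_rate, kin.theta_ref_acc,
                          weight=10.0)],
        )
        q, v = np.zeros(6), np.zeros(6)
        q[0] = float(kin.theta_ref(0.0))
        acts = {"plantarflexors": 0.0, "dorsiflexors": 0.0}
        t = 0.0
        worst = 0.0
        for _ in range(600):
            st = State(q, v, acts, t)
            controls, _ = controller.solve(st, t, 1e-3)
            acts = controller.advance_activations(st, controls["activations"], 1e-3)
            q, v, _ = engine.step(q, v, t, {"activations": acts, "reserves": controls["reserves"]})
            t += 1e-3
            for disp in engine.marker_displacements(q).values():
                worst = max(worst, float(np.max(np.abs(disp))))
        assert worst < 6e-3


class TestRunGaitCycle:
    def test_determinism_identical_checksums(self, model):
        mod = apply_weakening(model, "PF50")
        trial = synth_gait("medium", 3).with_support(synth_support("PF50", "medium", 3))
        r1 = run_gait_cycle(mod, trial)
        r2 = run_gait_cycle(mod, trial)
        assert r1.checksum() == r2.checksum()

    def test_result_record_structure(self, pf25_result):
        res = pf25_result
        n = len(res.time)
        assert res.q.shape == (n, 6)
        assert set(res.marker_disp) == {"foot", "shank"}
        assert set(res.wrenches) == {"foot_instep", "foot_heel", "tibia_strap", "tibia_rim"}
        assert "ankle_rz" in res.residuals and "base_fx" in res.residuals
        assert np.all(res.residuals["base_fx"] == 0.0)
        assert np.all((res.phase >= 0) & (res.phase <= 100))
        for name, arr in res.activations.items():
            assert np.all((arr >= 0) & (arr <= 1)), name

    def test_stance_mask_uses_two_percent_threshold(self, pf25_result):
        mask = pf25_result.stance_mask()
        frac = mask.mean()
        assert 0.5 < frac < 0.7  # roughly the stance fraction of the cycle
        assert not mask[-1]  # swing at the end of the cycle

    def test_partial_result_and_diagnostic_on_failure(self, model):
        mod = apply_weakening(model, "PF50")
        trial = synth_gait("slow", 2)
        bad_support = type(
            "Bad", (), {"at_phase": staticmethod(lambda ph: np.where(ph > 20.0, np.nan, 0.0))}
        )()
        trial = trial.with_support(bad_support)
        res = run_gait_cycle(mod, trial)
        assert len(res.time) < int(trial.cycle_duration / 1e-3) - 1
        assert any("integration failure" in msg for _, msg in res.flags)

    def test_save_round_trip(self, pf25_result, tmp_path):
        pf25_result.save(tmp_path / "cond")
        frame_csv = (tmp_path / "cond" / "trial.csv").read_text().splitlines()
        assert len(frame_csv) == len(pf25_result.time) + 1
        import json

        meta = json.loads((tmp_path / "cond" / "trial.json").read_text())
        assert meta["checksum"] == pf25_result.checksum()
        assert meta["level"] == "PF25"
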
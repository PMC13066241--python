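"""Unit tests of the viscoelastic interface element (per-axis bushing law)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afoflex.interface_model import (
    BushingParams,
    FramePose,
    Wrench,
    bushing_wrench,
    default_interface_params,
    interface_power,
    interface_power_split,
    spring_energy,
)

finite = st.floats(-1.0, 1.0, allow_nan=False, allow_infinity=False)
vec3 = st.tuples(finite, finite, finite).map(np.array)


def _random_params(rng):
    return BushingParams(
        k_trans=rng.uniform(0, 1e4, 3),
        k_rot=rng.uniform(0, 500, 3),
        c_trans=rng.uniform(0, 10, 3),
        c_rot=rng.uniform(0, 10, 3),
    )


class TestDefaults:
    @pytest.mark.parametrize(
        "site, k_trans, k_rot",
        [
            ("tibia", (100.0, 10_000.0, 100.0), (200.0, 500.0, 200.0)),
            ("foot", (10_000.0, 500.0, 500.0), (500.0, 200.0, 200.0)),
        ],
    )
    def test_stiffness_table(self, site, k_trans, k_rot):
        p = default_interface_params(site)
        assert tuple(p.k_trans) == k_trans
        assert tuple(p.k_rot) == k_rot

    def test_single_damping_value_everywhere(self):
        for site in ("tibia", "foot"):
            p = default_interface_params(site)
            assert np.all(p.c_trans == 5.0)
            assert np.all(p.c_rot == 5.0)

    def test_unknown_site_lists_valid_sites(self):
        with pytest.raises(ValueError, match="tibia.*foot|foot.*tibia"):
            default_interface_params("thigh")

    def test_serialization_round_trip_is_bit_exact(self):
        for site in ("tibia", "foot"):
            p = default_interface_params(site)
            q = BushingParams.from_dict(p.as_dict())
            for attr in ("k_trans", "k_rot", "c_trans", "c_rot"):
                assert np.array_equal(getattr(p, attr), getattr(q, attr))

    def test_unit_mismatch_rejected(self):
        data = default_interface_params("foot").as_dict()
        data["units"]["k_trans"] = "N/mm"
        with pytest.raises(ValueError, match="unit mismatch.*k_trans"):
            BushingParams.from_dict(data)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError, match="k_rot.*non-negative"):
            BushingParams(k_trans=np.ones(3), k_rot=[1.0, -2.0, 1.0])


class TestBushingLaw:
    def test_zero_deviation_gives_zero_wrench(self):
        w = bushing_wrench(default_interface_params("tibia"), FramePose(), FramePose())
        assert np.all(w.force == 0) and np.all(w.moment == 0)

    def test_tibia_two_millimetres_vertical_gives_minus_twenty_newtons(self):
        # hand oracle: 10,000 N/m * 0.002 m = 20 N restoring
        w = bushing_wrench(
            default_interface_params("tibia"),
            FramePose(position=[0.0, 0.002, 0.0]),
            FramePose(),
        )
        assert w.force[1] == pytest.approx(-20.0)
        assert w.force[0] == 0.0 and w.force[2] == 0.0
        assert np.all(w.moment == 0)

    def test_spring_and_damper_moments_oppose_for_opposing_signs(self):
        p = default_interface_params("foot")
        pose = FramePose(rotation=[0.0, 0.0, 0.1])
        vel = FramePose(rotation=[0.0, 0.0, -0.5])
        spring_only = bushing_wrench(
            BushingParams(p.k_trans, p.k_rot, np.zeros(3), np.zeros(3)), pose, FramePose()
        )
        damper_only = bushing_wrench(
            BushingParams(np.zeros(3), np.zeros(3), p.c_trans, p.c_rot), FramePose(), vel
        )
        assert spring_only.moment[2] * damper_only.moment[2] < 0

    def test_per_axis_law_matches_hand_formula(self, rng):
        # independent oracle: the scalar law written out directly
        for _ in range(20):
            p = _random_params(rng)
            dx, dth = rng.normal(0, 0.01, 3), rng.normal(0, 0.05, 3)
            vx, vth = rng.normal(0, 0.1, 3), rng.normal(0, 0.5, 3)
            w = bushing_wrench(p, FramePose(dx, dth), FramePose(vx, vth))
            for i in range(3):
                assert w.force[i] == pytest.approx(
                    -(p.k_trans[i] * dx[i] + p.c_trans[i] * vx[i]), rel=1e-12
                )
                assert w.moment[i] == pytest.approx(
                    -(p.k_rot[i] * dth[i] + p.c_rot[i] * vth[i]), rel=1e-12
                )

    @given(pos=vec3, rot=vec3, alpha=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_spring_part_is_linear(self, pos, rot, alpha):
        p = BushingParams(
            k_trans=[100.0, 1e4, 500.0], k_rot=[200.0, 500.0, 200.0],
            c_trans=np.zeros(3), c_rot=np.zeros(3),
        )
        w1 = bushing_wrench(p, FramePose(pos, rot), FramePose())
        w2 = bushing_wrench(p, FramePose(alpha * pos, alpha * rot), FramePose())
        np.testing.assert_allclose(w2.force, alpha * w1.force, atol=1e-09)
        np.testing.assert_allclose(w2.moment, alpha * w1.moment, atol=1e-09)

    def test_action_reaction(self, rng):
        p = _random_params(rng)
        w = bushing_wrench(p, FramePose(rng.normal(0, 0.01, 3)), FramePose(rng.normal(0, 0.1, 3)))
        reaction = -w
        assert np.all(w.force + reaction.force == 0)
        assert np.all(w.moment + reaction.moment == 0)

    def test_axis_decoupling(self):
        p = default_interface_params("foot")
        base = bushing_wrench(p, FramePose(), FramePose())
        for i in range(3):
            dx = np.zeros(3)
            dx[i] = 0.01
            w = bushing_wrench(p, FramePose(position=dx), FramePose())
            changed = np.flatnonzero(w.force != base.force)
            assert list(changed) == [i]
            assert np.all(w.moment == base.moment)

    def test_non_finite_input_names_axis(self):
        with pytest.raises(ValueError, match="axis y|position"):
            bushing_wrench(
                default_interface_params("foot"),
                FramePose(position=[0.0, np.nan, 0.0]),
                FramePose(),
            )


class TestPower:
    def test_zero_velocity_zero_power(self):
        w = Wrench(force=np.array([1.0, 2.0, 3.0]), moment=np.zeros(3))
        assert interface_power(w, FramePose()) == 0.0

    def test_frame_mismatch_rejected(self):
        w = Wrench(force=np.ones(3), moment=np.zeros(3), frame="element")
        with pytest.raises(ValueError, match="frame mismatch"):
            interface_power(w, FramePose(), frame="world")

    @given(v=vec3, w=vec3)
    @settings(max_examples=50, deadline=None)
    def test_damper_dissipation_is_non_negative(self, v, w):
        p = default_interface_params("tibia")
        _, dissipated = interface_power_split(p, FramePose(), FramePose(v, w))
        assert dissipated >= 0.0
        # closed form: sum c_i v_i^2
        assert dissipated == pytest.approx(
            float(p.c_trans @ v**2 + p.c_rot @ w**2), rel=1e-12
        )

    def test_harmonic_cycle_spring_work_vanishes(self):
        # quadrature oracle: integrate spring power over one full cycle
        p = BushingParams(
            k_trans=[100.0, 1e4, 500.0], k_rot=[200.0, 500.0, 200.0],
            c_trans=np.zeros(3), c_rot=np.zeros(3),
        )
        t = np.linspace(0.0, 1.0, 4001)
        amp = np.array([0.01, 0.002, 0.005])
        powers = []
        for ti in t:
            pos = amp * np.sin(2 * np.pi * ti)
            vel = amp * 2 * np.pi * np.cos(2 * np.pi * ti)
            sp, _ = interface_power_split(p, FramePose(position=pos), FramePose(position=vel))
            powers.append(sp)
        net = np.trapezoid(powers, t)
        scale = np.trapezoid(np.abs(powers), t)
        assert abs(net) < 1e-06 * max(scale, 1.0)

    def test_spring_power_is_energy_rate(self, rng):
        p = _random_params(rng)
        pose = FramePose(rng.normal(0, 0.01, 3), rng.normal(0, 0.05, 3))
        vel = FramePose(rng.normal(0, 0.1, 3), rng.normal(0, 0.5, 3))
        sp, _ = interface_power_split(p, pose, vel)
        eps = 1e-07
        e0 = spring_energy(p, pose)
        e1 = spring_energy(
            p,
            FramePose(pose.position + eps * vel.position, pose.rotation + eps * vel.rotation),
        )
        assert sp == pytest.approx((e1 - e0) / eps, rel=1e-05, abs=1e-08)
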
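"""Distribution gains, overloading joint torques and level classification."""

import numpy as np
import pytest

from ergoload import (
    ExternalLoad,
    Posture,
    assess_overload,
    classify_level,
    distribution_gains,
    forward_kinematics,
    frame_point_jacobian,
    overloading_torques,
    point_jacobian,
    point_on_link,
    simulate_statics,
)
from ergoload.overload import GREEN, ORANGE, RED
from ergoload.simulator import load_world_x, place_load, sample_posture

from conftest import arm_posture, make_arm


def _ankle_xs(model, posture):
    segs = {s.link: s for s in forward_kinematics(model, posture)}
    return [segs[f].proximal[0] for f in model.foot_links]


def _asymmetric_posture(model):
    """Split stance: one leg forward, the other back."""
    q = np.zeros(model.n_joints)
    q[model.joint_index("l_hip")] = 0.5
    q[model.joint_index("r_hip")] = -0.3
    return Posture(np.array([0.0, 0.9]), 0.0, q)


class TestDistributionGains:
    def test_symmetric_stance_splits_evenly(self, model):
        p = Posture(np.array([0.0, 0.9]), 0.0, np.zeros(model.n_joints))
        g = distribution_gains(model, p, cop_x=0.1)
        np.testing.assert_allclose(g.zeta, [0.5, 0.5])

    def test_cop_at_one_ankle_loads_that_foot(self, model):
        p = _asymmetric_posture(model)
        xl, xr = _ankle_xs(model, p)
        g = distribution_gains(model, p, cop_x=xl)
        np.testing.assert_allclose(g.zeta, [1.0, 0.0], atol=1e-12)

    def test_quarter_way_interpolation(self, model):
        p = _asymmetric_posture(model)
        xl, xr = _ankle_xs(model, p)
        g = distribution_gains(model, p, cop_x=xl + 0.25 * (xr - xl))
        np.testing.assert_allclose(g.zeta, [0.75, 0.25], atol=1e-12)

    def test_gains_always_sum_to_one(self, model, rng):
        for _ in range(20):
            p = sample_posture(model, rng, symmetric=False)
            g = distribution_gains(model, p, cop_x=rng.uniform(-0.5, 0.5))
            assert float(np.sum(g.zeta)) == pytest.approx(1.0, abs=1e-12)
            assert np.all(g.zeta >= 0) and np.all(g.zeta <= 1)


def _direct_static_difference(model, posture, load, cop_wt, cop_wo,
                              f_wt, gains):
    """Independent oracle: loaded-minus-unloaded static joint torques by
    plain Jacobian-transpose statics (gravity terms cancel)."""
    fh = load.force_vec
    f_wo_vec = np.array([0.0, f_wt]) + fh  # unloaded vGRF vector
    segs = forward_kinematics(model, posture)
    tau_wt = -point_jacobian(model, posture, load.link, load.position,
                             segs).matrix.T @ fh
    for z, foot in zip(gains.zeta, gains.feet):
        J_wt = frame_point_jacobian(model, posture, foot,
                                    np.array([cop_wt, 0.0]), segs)
        J_wo = frame_point_jacobian(model, posture, foot,
                                    np.array([cop_wo, 0.0]), segs)
        tau_wt = tau_wt - J_wt.matrix.T @ (z * np.array([0.0, f_wt]))
        # unloaded state: same gains, unloaded CoP and force
        tau_wt = tau_wt + J_wo.matrix.T @ (z * f_wo_vec)
    return tau_wt[3:]


class TestOverloadingTorques:
    def test_no_load_and_matching_cop_gives_zero(self, model, rng):
        p = sample_posture(model, rng)
        load = ExternalLoad((0.0, 0.0), "FA", 0.2)
        gains = distribution_gains(model, p, 0.05)
        dtau = overloading_torques(model, p, load, 0.05, 0.05, 700.0, gains)
        np.testing.assert_allclose(dtau, 0.0, atol=1e-12)

    def test_matches_direct_static_difference(self, model, rng):
        for _ in range(20):
            p = sample_posture(model, rng, symmetric=False)
            link = ["FA", "UA", "T"][rng.integers(3)]
            load = place_load(model, p, link, rng.uniform(0.1, 0.9), 5.0)
            st = simulate_statics(model, p, load)
            gains = distribution_gains(model, p, st.cop_loaded)
            dtau = overloading_torques(model, p, load, st.cop_loaded,
                                       st.cop_unloaded, st.vgrf_loaded, gains)
            oracle = _direct_static_difference(
                model, p, load, st.cop_loaded, st.cop_unloaded,
                st.vgrf_loaded, gains)
            np.testing.assert_allclose(dtau, oracle, atol=1e-9)

    def test_shoulder_moment_arm(self):
        """40 N vertical load 0.3 m from the shoulder axis: 12 N m."""
        arm = make_arm(l1=0.3, l2=0.4)
        pose = arm_posture(0.0, 0.3)
        segs = {s.link: s for s in forward_kinematics(arm, pose)}
        shoulder_x = segs["upper"].proximal[0]
        # find the link point 0.3 m horizontally from the shoulder
        target_x = shoulder_x + 0.3
        s_lo = (target_x - segs["lower"].proximal[0]) / segs["lower"].axis[0]
        load = ExternalLoad((0.0, -40.0), "lower", s_lo)
        from ergoload import DistributionGains
        gains = DistributionGains(np.array([1.0]), ["root"])
        cop = 0.0  # measured == estimated: the CoP-displacement terms vanish
        dtau = overloading_torques(arm, pose, load, cop, cop, 740.0, gains)
        assert abs(dtau[arm.joint_index("shoulder")]) == pytest.approx(
            12.0, abs=1e-9)

    def test_linearity_in_load_magnitude(self, model, rng):
        p = sample_posture(model, rng)
        load1 = place_load(model, p, "FA", 0.6, 3.0)
        load2 = place_load(model, p, "FA", 0.6, 6.0)
        st1 = simulate_statics(model, p, load1)
        st2 = simulate_statics(model, p, load2)
        gains = distribution_gains(model, p, st1.cop_unloaded)
        d1 = overloading_torques(model, p, load1, st1.cop_loaded,
                                 st1.cop_unloaded, st1.vgrf_loaded, gains)
        d2 = overloading_torques(model, p, load2, st2.cop_loaded,
                                 st2.cop_unloaded, st2.vgrf_loaded, gains)
        np.testing.assert_allclose(d2, 2.0 * d1, atol=1e-9)

    def test_load_outside_link_raises(self, model, rng):
        p = sample_posture(model, rng)
        bad = ExternalLoad((0.0, -40.0), "FA", 0.9)  # FA is 0.46 m
        gains = distribution_gains(model, p, 0.0)
        with pytest.raises(ValueError):
            overloading_torques(model, p, bad, 0.0, 0.0, 700.0, gains)


class TestClassifyLevel:
    @pytest.mark.parametrize("frac,level", [
        (0.0, GREEN), (0.2, GREEN), (0.3, GREEN),
        (0.300001, ORANGE), (0.6, ORANGE), (0.7, RED), (1.0, RED),
    ])
    def test_stepwise_bands(self, frac, level):
        lvl, over = classify_level(frac * 150.0, 150.0)
        assert lvl == level
        assert not over

    def test_sign_is_ignored(self):
        assert classify_level(-0.5 * 80.0, 80.0)[0] == ORANGE

    def test_over_limit_clamps_to_red_with_flag(self):
        lvl, over = classify_level(200.0, 150.0)
        assert lvl == RED and over

    def test_nonpositive_capacity_raises(self):
        with pytest.raises(ValueError):
            classify_level(1.0, 0.0)


def test_assess_overload_end_to_end(model, rng):
    p = sample_posture(model, rng)
    load = place_load(model, p, "FA", 0.67, 5.0)
    st = simulate_statics(model, p, load)
    result = assess_overload(model, p, load, st.cop_loaded, st.cop_unloaded,
                             st.vgrf_loaded)
    assert result.joints == model.joints
    assert len(result.levels) == model.n_joints
    assert set(result.levels) <= {GREEN, ORANGE, RED}
    # a 5 kg hand load must torque the elbow and shoulder
    assert abs(result.delta_tau[model.joint_index("elbow")]) > 0.1
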
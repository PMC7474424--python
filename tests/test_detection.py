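"""Contact-point formula, link intersection, Anderson-Darling statistic,
confidence-interval stopping and the online detection loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ergoload import (
    DetectionConfig,
    DetectionState,
    ForcePlateSample,
    LinkSegment2D,
    NotCalibratedError,
    ScenarioSpec,
    ad_statistic,
    confidence_halfwidth,
    contact_x,
    detect_step,
    link_intersections,
    run_detection,
    simulate_statics,
    standing_model,
    stream_frame,
    true_parameters,
)
from ergoload.io import plates_from_stream, postures_from_stream
from ergoload.simulator import place_load, load_world_x, sample_posture


class TestContactX:
    def test_collinear_load_returns_unloaded_cop(self):
        assert contact_x(0.12, 700.0, 0.12, 650.0) == pytest.approx(0.12)

    def test_forward_statics_composition(self):
        cop_wt = (0.10 * 600 + 0.40 * 40) / 640
        assert contact_x(cop_wt, 640.0, 0.10, 600.0) == pytest.approx(
            0.40, abs=1e-12)

    @given(cop_wo=st.floats(-0.3, 0.3), x=st.floats(-0.5, 0.8),
           f_wo=st.floats(400, 900), f_load=st.floats(10, 300))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_and_swap_symmetry(self, cop_wo, x, f_wo, f_load):
        f_wt = f_wo + f_load
        cop_wt = (cop_wo * f_wo + x * f_load) / f_wt
        forward = contact_x(cop_wt, f_wt, cop_wo, f_wo)
        assert forward == pytest.approx(x, abs=1e-9)
        assert contact_x(cop_wo, f_wo, cop_wt, f_wt) == pytest.approx(
            forward, abs=1e-9)

    def test_simulator_round_trip(self, model, rng):
        for _ in range(50):
            posture = sample_posture(model, rng)
            load = place_load(model, posture, "FA", rng.uniform(0.1, 0.9), 4.0)
            st_ = simulate_statics(model, posture, load)
            x = contact_x(st_.cop_loaded, st_.vgrf_loaded,
                          st_.cop_unloaded, st_.vgrf_unloaded)
            assert x == pytest.approx(load_world_x(model, posture, load),
                                      abs=1e-12)


class TestLinkIntersections:
    def _fa(self):
        return LinkSegment2D("FA", np.array([0.2, 1.0]), np.array([0.5, 1.0]),
                             np.eye(2))

    def _ua(self):
        return LinkSegment2D("UA", np.array([0.3, 1.5]), np.array([0.4, 1.0]),
                             np.eye(2))  # rotation unused by intersection

    def test_no_intersection_beyond_body(self):
        assert link_intersections([self._fa()], 5.0, ["FA"]) == []

    def test_horizontal_forearm_local_coordinate(self):
        hits = link_intersections([self._fa()], 0.35, ["FA"])
        assert len(hits) == 1
        link, local = hits[0]
        assert link == "FA" and local == pytest.approx(0.15, abs=1e-12)

    def test_multiple_crossings_ordered_per_candidates(self):
        segs = [self._fa(), self._ua()]
        hits = link_intersections(segs, 0.35, ["UA", "FA"])
        assert [h[0] for h in hits] == ["UA", "FA"]


class TestAndersonDarling:
    FIXED = [-1.2, -0.7, -0.3, -0.1, 0.2, 0.4, 0.9, 1.5]

    @staticmethod
    def _oracle(samples):
        """Direct term-by-term summation of the weighted log-CDF form."""
        x = sorted(samples)
        n = len(x)
        mu = sum(x) / n
        sd = math.sqrt(sum((v - mu) ** 2 for v in x) / (n - 1))
        s = [(v - mu) / sd for v in x]
        F = [stats.norm.cdf(v) for v in s]
        total = 0.0
        for i in range(1, n + 1):
            total += (2 * i - 1) / n * (
                math.log(F[i - 1]) + math.log(1.0 - F[n - i]))
        return -n - total

    def test_matches_direct_summation_oracle(self):
        assert ad_statistic(self.FIXED) == pytest.approx(
            self._oracle(self.FIXED), abs=1e-12)

    def test_matches_scipy_reference(self, rng):
        for _ in range(5):
            x = rng.normal(size=60)
            assert ad_statistic(x) == pytest.approx(
                stats.anderson(x, "norm").statistic, abs=1e-10)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        base = ad_statistic(self.FIXED)
        scaled = ad_statistic([a * v + b for v in self.FIXED])
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_zero_variance_is_degenerate_accept(self):
        assert ad_statistic([0.2] * 10) == 0.0

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            ad_statistic([0.1, 0.2])

    def test_acceptance_rule_against_default_critical_value(self):
        config = DetectionConfig()
        assert 0.5 < config.ad_critical  # normality accepted
        assert not (1.0 < config.ad_critical)  # rejected


class TestConfidenceHalfwidth:
    def test_zero_spread(self):
        assert confidence_halfwidth(0.0, 7, 1.96) == 0.0

    def test_direct_evaluation(self):
        hw = confidence_halfwidth(0.05, 100, 1.96)
        assert hw == pytest.approx(0.0098, abs=1e-12)
        assert hw < DetectionConfig().ci_threshold

    def test_inverse_sqrt_n_scaling(self):
        assert confidence_halfwidth(0.03, 400, 1.96) == pytest.approx(
            confidence_halfwidth(0.03, 100, 1.96) / 2, abs=1e-15)


def _noiseless_scenario(**kw):
    return ScenarioSpec(noise_cop=0.0, noise_force=0.0, sway_amplitude=0.0,
                        keypose_s=1e9, **kw)


def _run(model, scenario, link, fraction, config):
    df = stream_frame(model, scenario, link=link, fraction=fraction)
    return run_detection(model, true_parameters(model),
                         postures_from_stream(df, model),
                         plates_from_stream(df), config)


class TestDetectStep:
    def test_uncalibrated_raises(self, model, rng):
        posture = sample_posture(model, rng)
        with pytest.raises(NotCalibratedError):
            detect_step(DetectionState(), posture,
                        ForcePlateSample(0.0, 0.0, 700.0), None, model,
                        DetectionConfig())

    def test_unloaded_stream_accumulates_nothing(self, model):
        sc = _noiseless_scenario(seed=11, loaded_s=10.0)
        df = stream_frame(model, sc, link=None)
        est, state, _ = run_detection(
            model, true_parameters(model), postures_from_stream(df, model),
            plates_from_stream(df), DetectionConfig(filter_window=1))
        assert est is None
        assert state.per_link == {}

    def test_noiseless_midforearm_latches_and_recovers_truth(self, model):
        """Exact statics: FA latches at the first test (n = n_min + 1) and
        the degenerate spread stops the episode immediately."""
        sc = _noiseless_scenario(seed=5, load_mass=4.0, loaded_s=10.0)
        config = DetectionConfig(filter_window=1)
        est, state, _ = _run(model, sc, "FA", 0.5, config)
        assert est is not None and est.link == "FA"
        assert est.n_used == config.n_min + 1
        assert est.position == pytest.approx(
            0.5 * model.segment("FA").length, abs=1e-6)

    def test_latch_is_permanent_within_episode(self, model):
        sm = standing_model(model)
        sc = ScenarioSpec(seed=9001)
        df = stream_frame(sm, sc, link="FA", fraction=0.31 / 0.46)
        postures = postures_from_stream(df, sm)
        plates = plates_from_stream(df)
        state = DetectionState()
        config = DetectionConfig()
        params = true_parameters(sm)
        latched = []
        for posture, plate in zip(postures, plates):
            detect_step(state, posture, plate, params, sm, config)
            if state.latched_link is not None:
                latched.append(state.latched_link)
        assert latched and len(set(latched)) == 1

    @pytest.mark.parametrize("seed", [100, 103, 109])
    def test_noisy_position_accurate_when_link_latched(self, model, seed):
        """Sensor noise of 5 mm / 5 N: whenever the forearm is correctly
        latched, the hands-position estimate lands within 10% of 0.31 m."""
        sm = standing_model(model)
        est, state, _ = _run(sm, ScenarioSpec(seed=seed), "FA", 0.31 / 0.46,
                             DetectionConfig())
        if state.latched_link == "FA" and est is not None:
            assert abs(est.position - 0.31) <= 0.1 * 0.31
            assert 0.0 <= est.position <= sm.segment("FA").length
            assert est.n_used > DetectionConfig().n_min

    def test_stopping_threshold_tradeoff_small(self, model):
        """A looser confidence threshold never stops later on one stream."""
        sm = standing_model(model)
        sc = ScenarioSpec(seed=77, loaded_s=90.0)
        df = stream_frame(sm, sc, link="FA", fraction=0.31 / 0.46)
        postures = postures_from_stream(df, sm)
        plates = plates_from_stream(df)
        params = true_parameters(sm)
        times = []
        for thr in (0.005, 0.02):
            est, _, _ = run_detection(sm, params, postures, plates,
                                      DetectionConfig(ci_threshold=thr))
            times.append(math.inf if est is None else est.elapsed)
        assert times[0] >= times[1]
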
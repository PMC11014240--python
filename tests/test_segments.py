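import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cwmsim.rng import child_rng
from cwmsim.segments import (
    SEGMENT_NAMES,
    SegmentTooShortError,
    logistic_rate,
    rescale_to_interval,
    sample_segment_params,
    seg_cosine_gt,
    seg_exp_decay,
    seg_logistic,
    seg_rayleigh,
    seg_sine_th,
    seg_sinusoid_pb,
    seg_skew_gauss_hk,
    synthesize_cycle_velocity,
)
from cwmsim.timing import (
    place_keypoints,
    sample_cycle_length,
    sample_phase_durations,
    sample_velocity_keypoints,
)


def draw_cycle(seed=1, fs=100.0):
    rt = child_rng(seed, "timing")
    rv = child_rng(seed, "velocity")
    timing = sample_phase_durations(rt, sample_cycle_length(rt))
    schedule = place_keypoints(rt, timing)
    vk = sample_velocity_keypoints(rv)
    params = sample_segment_params(rv, timing, schedule)
    return timing, schedule, vk, params, fs


class TestRescale:
    def test_affine_endpoints(self):
        out = rescale_to_interval(np.array([0.0, 0.5, 1.0]), -0.05, 0.02)
        np.testing.assert_allclose(out, [-0.05, -0.015, 0.02], atol=1e-15)

    def test_identity_when_interval_matches(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(
            rescale_to_interval(x, x.min(), x.max()), x, atol=1e-12)

    def test_constant_maps_to_midpoint(self):
        np.testing.assert_allclose(
            rescale_to_interval(np.array([3.0, 3.0, 3.0]), 0.0, 2.0), [1.0, 1.0, 1.0])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rescale_to_interval(np.array([]), 0.0, 1.0)

    def test_inverted_interval_raises(self):
        with pytest.raises(ValueError):
            rescale_to_interval(np.array([1.0, 2.0]), 1.0, 0.0)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
           st.floats(-10, 10), st.floats(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_extremes_exact_and_order_preserved(self, values, v_min, width):
        x = np.array(values)
        if x.max() == x.min():
            return
        v_max = v_min + width
        out = rescale_to_interval(x, v_min, v_max)
        assert out.min() == pytest.approx(v_min, abs=1e-9)
        assert out.max() == pytest.approx(v_max, abs=1e-9)
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-12)


class TestSegmentShapes:
    """Every shape checked against a direct formula evaluation."""

    def test_pb_phase_at_origin(self):
        y = seg_sinusoid_pb(0.1, 1000.0, theta=math.pi / 6, alpha=1.5)
        assert y[0] == pytest.approx(math.sin(math.pi / 6))

    def test_pb_half_period_at_alpha_two(self):
        y = seg_sinusoid_pb(0.1, 1000.0, theta=0.0, alpha=2.0,
                            t=np.array([0.1]))
        assert y[0] == pytest.approx(math.sin(math.pi), abs=1e-12)

    def test_pb_matches_formula_pointwise(self, rng):
        L, fs = 0.1, 1000.0
        theta, alpha = math.pi / 4, 4.0 / 3.0
        y = seg_sinusoid_pb(L, fs, theta, alpha)
        t = np.arange(round(L * fs)) / fs
        np.testing.assert_allclose(
            y, np.sin(2 * math.pi * t / (alpha * L) + theta), atol=1e-14)

    def test_logistic_rate_solves_saturation(self):
        k = logistic_rate(0.1, 0.9)
        assert k == pytest.approx(2 * math.log(9) / 0.1, rel=1e-12)
        assert k == pytest.approx(43.944, abs=1e-3)

    def test_logistic_midpoint_and_endpoints(self):
        L = 0.05
        y = seg_logistic(L, 1000.0, 0.99, t=np.array([0.0, L / 2, L]))
        assert y[1] == pytest.approx(0.5)
        assert y[2] == pytest.approx(0.99, abs=1e-12)
        assert y[0] == pytest.approx(0.01, abs=1e-12)

    def test_logistic_strictly_increasing(self):
        y = seg_logistic(0.1, 1000.0, 0.9)
        assert np.all(np.diff(y) > 0)

    def test_exp_decay_rate_and_endpoints(self):
        L = 0.05
        y = seg_exp_decay(L, 1000.0, 0.01, t=np.array([0.0, L]))
        assert y[0] == pytest.approx(1.0)
        assert y[1] == pytest.approx(0.01, abs=1e-12)
        # k = ln(100)/0.05 ~ 92.103
        assert -math.log(0.01) / L == pytest.approx(92.103, abs=1e-3)

    def test_exp_decay_target_validation(self):
        with pytest.raises(ValueError):
            seg_exp_decay(0.1, 1000.0, 1.5)

    def test_rayleigh_origin_peak_location_and_height(self):
        sigma = 0.025
        y = seg_rayleigh(0.2, 10_000.0, sigma)
        t = np.arange(y.size) / 10_000.0
        assert y[0] == 0.0
        assert t[np.argmax(y)] == pytest.approx(sigma, abs=1e-4)
        assert y.max() == pytest.approx(math.exp(-0.5) / sigma, rel=1e-4)

    def test_cosine_gt_start_and_half_turn(self):
        L = 0.1
        y = seg_cosine_gt(L, 1000.0, 0.5, t=np.array([0.0, L]))
        assert y[0] == pytest.approx(1.0)
        assert y[1] == pytest.approx(-1.0)

    def test_cosine_gt_monotone_for_small_alpha(self):
        y = seg_cosine_gt(0.1, 1000.0, 0.5)
        assert np.all(np.diff(y) < 0)

    def test_sine_th_starts_at_minimum(self):
        y = seg_sine_th(0.1, 1000.0, 1.5)
        assert y[0] == pytest.approx(-1.0)

    def test_sine_th_full_phase_arithmetic(self):
        L = 0.1
        y = seg_sine_th(L, 1000.0, 2.0, t=np.array([L]))
        # phase = pi + 3pi/2 = 5pi/2 -> sin = 1
        assert y[0] == pytest.approx(1.0, abs=1e-12)

    def test_sine_th_increasing_on_first_quarter(self):
        L, r_th = 0.1, 1.5
        y = seg_sine_th(L, 10_000.0, r_th)
        t = np.arange(y.size) / 10_000.0
        quarter = t <= r_th * L / 4
        assert np.all(np.diff(y[quarter]) > 0)

    def test_skew_gauss_symmetric_when_gamma_zero(self):
        mu, sigma = 0.05, 0.02
        d = np.array([0.005, 0.01, 0.015])
        left = seg_skew_gauss_hk(0.1, 1000.0, mu, sigma, 0.0, t=mu - d)
        right = seg_skew_gauss_hk(0.1, 1000.0, mu, sigma, 0.0, t=mu + d)
        np.testing.assert_allclose(left, right, rtol=1e-12)

    def test_skew_gauss_peak_value(self):
        mu, sigma = 0.05, 0.02
        y = seg_skew_gauss_hk(0.1, 1000.0, mu, sigma, 0.3, t=np.array([mu]))
        assert y[0] == pytest.approx(1.0 / math.sqrt(2 * math.pi * sigma**2))

    def test_skew_gauss_cubic_asymmetry_ratio(self):
        mu, sigma, gamma = 0.05, 0.02, -0.5
        yp = seg_skew_gauss_hk(0.1, 1000.0, mu, sigma, gamma, t=np.array([mu + sigma]))
        ym = seg_skew_gauss_hk(0.1, 1000.0, mu, sigma, gamma, t=np.array([mu - sigma]))
        assert yp[0] / ym[0] == pytest.approx(3.0, rel=1e-12)

    @pytest.mark.parametrize("fn, args", [
        (seg_sinusoid_pb, (math.pi / 6, 1.5)),
        (seg_logistic, (0.9,)),
        (seg_exp_decay, (0.01,)),
        (seg_rayleigh, (0.02,)),
        (seg_cosine_gt, (0.5,)),
        (seg_sine_th, (1.5,)),
    ])
    def test_too_few_samples_raises(self, fn, args):
        with pytest.raises(SegmentTooShortError):
            fn(0.01, 100.0, *args)


class TestCycleAssembly:
    def test_sample_count(self):
        timing, schedule, vk, params, fs = draw_cycle(seed=2)
        trace = synthesize_cycle_velocity(timing, schedule, vk, params, fs)
        assert trace.n == round(timing.cycle_len * fs)

    def test_segments_tile_without_gaps(self):
        timing, schedule, vk, params, fs = draw_cycle(seed=2)
        trace = synthesize_cycle_velocity(timing, schedule, vk, params, fs)
        seg_idx = trace.meta["segment_index"]
        assert list(seg_idx) == list(SEGMENT_NAMES)
        spans = list(seg_idx.values())
        assert spans[0][0] == 0
        assert spans[-1][1] == trace.n
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c

    def test_segment_extremes_hit_keypoints(self):
        timing, schedule, vk, params, fs = draw_cycle(seed=4, fs=500.0)
        trace = synthesize_cycle_velocity(timing, schedule, vk, params, fs)
        seg_idx = trace.meta["segment_index"]
        expected = {
            "pb": (vk.v_b, vk.v_afp),
            "bc": (vk.v_b, vk.v_aop),
            "cj": (vk.v_j, vk.v_aop),
            "je": (vk.v_j, vk.v_e),
            "ef": (vk.v_f, vk.v_e),
            "fg": (vk.v_f, vk.v_g),
            "th": (vk.v_t, vk.v_h),
            "hk": (vk.v_ivrv, vk.v_ivrp),
            "fill": (0.0, vk.v_rpf),
        }
        for name, (lo, hi) in expected.items():
            a, b = seg_idx[name]
            seg = trace.samples[a:b]
            assert seg.min() == pytest.approx(lo, abs=1e-12), name
            assert seg.max() == pytest.approx(hi, abs=1e-12), name

    def test_gt_segment_anchored_to_fg_endpoint(self):
        timing, schedule, vk, params, fs = draw_cycle(seed=4, fs=500.0)
        trace = synthesize_cycle_velocity(timing, schedule, vk, params, fs)
        a, b = trace.meta["segment_index"]["gt"]
        fg_end = trace.samples[trace.meta["segment_index"]["fg"][1] - 1]
        assert trace.samples[a:b].max() == pytest.approx(fg_end, abs=1e-12)
        assert trace.samples[a:b].min() == pytest.approx(vk.v_t, abs=1e-12)

    def test_velocity_starts_and_ends_near_zero(self):
        for seed in range(5):
            timing, schedule, vk, params, fs = draw_cycle(seed=seed, fs=200.0)
            trace = synthesize_cycle_velocity(timing, schedule, vk, params, fs)
            assert abs(trace.samples[0]) <= max(abs(vk.v_b), vk.v_afp) + 1e-12
            assert abs(trace.samples[-1]) <= 0.1

    def test_ejection_minimum_is_deepest_keypoint(self):
        timing, schedule, vk, params, fs = draw_cycle(seed=6, fs=500.0)
        trace = synthesize_cycle_velocity(timing, schedule, vk, params, fs)
        assert trace.samples.min() == pytest.approx(
            -max(abs(vk.v_j), abs(vk.v_f), abs(vk.v_t)), abs=1e-12)

    def test_low_fs_raises(self):
        timing, schedule, vk, params, _ = draw_cycle(seed=2)
        with pytest.raises(ValueError):
            synthesize_cycle_velocity(timing, schedule, vk, params, 10.0)

    def test_deterministic(self):
        a = synthesize_cycle_velocity(*draw_cycle(seed=11)[:4], 100.0)
        b = synthesize_cycle_velocity(*draw_cycle(seed=11)[:4], 100.0)
        np.testing.assert_array_equal(a.samples, b.samples)
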
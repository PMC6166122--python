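"""Per-parameter transform tests against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from discomfortlab import features as ft


class TestZscore:
    def test_three_point_series_forced_by_definition(self):
        z = ft.zscore(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z.z, [-1.0, 0.0, 1.0])
        assert not z.degenerate

    def test_constant_series_degenerates_to_zeros(self):
        z = ft.zscore(np.full(10, 4.2))
        np.testing.assert_array_equal(z.z, 0.0)
        assert z.degenerate

    def test_output_moments_match_direct_recomputation(self, rng):
        z = ft.zscore(rng.normal(3, 7, 500)).z
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9

    def test_missing_values_propagate(self, rng):
        v = rng.normal(size=50)
        v[[3, 7]] = np.nan
        z = ft.zscore(v).z
        assert np.isnan(z[[3, 7]]).all()
        assert np.isfinite(np.delete(z, [3, 7])).all()

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            ft.zscore(np.array([1.0, np.nan]))


class TestMovingAverageAndPupil:
    def test_unit_impulse_spreads_over_37_tick_window(self):
        v = np.zeros(200)
        v[100] = 1.0
        out = ft.moving_average(v, 18)
        hit = np.flatnonzero(out > 0)
        assert hit.size == 37
        np.testing.assert_allclose(out[hit], 1.0 / 37.0)

    def test_matches_brute_force_window_mean_with_missing(self, rng):
        v = rng.normal(size=300)
        v[rng.integers(0, 300, 40)] = np.nan
        out = ft.moving_average(v, 18)
        for i in [0, 5, 150, 281, 299]:  # brute-force oracle at spot ticks
            w = v[max(0, i - 18) : i + 19]
            w = w[~np.isnan(w)]
            if w.size:
                assert out[i] == pytest.approx(w.mean(), abs=1e-9)
            else:
                assert np.isnan(out[i])

    def test_binocular_mean_of_constant_eyes(self):
        left = np.full(100, 3.0)
        right = np.full(100, 4.0)
        np.testing.assert_allclose(ft.pupil_preprocess(left, right), 3.5)

    def test_constant_both_eyes_passes_through(self):
        v = np.full(100, 3.5)
        np.testing.assert_allclose(ft.pupil_preprocess(v, v.copy()), 3.5)

    def test_single_available_eye_used(self):
        left = np.full(100, 3.0)
        right = np.full(100, np.nan)
        np.testing.assert_allclose(ft.pupil_preprocess(left, right), 3.0)

    def test_both_eyes_missing_everywhere_stays_missing(self):
        nanv = np.full(50, np.nan)
        assert np.isnan(ft.pupil_preprocess(nanv, nanv.copy())).all()


class TestLuminance:
    def test_black_white_and_half_frames(self):
        assert ft.frame_luminance(np.zeros((4, 4, 3))) == 0.0
        assert ft.frame_luminance(np.ones((4, 4, 3))) == 1.0
        half = np.zeros((2, 2, 3))
        half[0] = 1.0
        assert ft.frame_luminance(half) == pytest.approx(0.5)

    def test_arbitrary_frame_matches_per_pixel_hand_computation(self, rng):
        px = rng.uniform(size=(5, 5, 3))
        want = np.mean(
            [(max(p) + min(p)) / 2.0 for row in px for p in row]
        )
        assert ft.frame_luminance(px) == pytest.approx(want, abs=1e-12)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            ft.frame_luminance(np.zeros((0, 3)))

    def test_adjust_identity_and_annihilation(self, rng):
        p = rng.normal(size=100)
        np.testing.assert_array_equal(ft.luminance_adjust(p, np.zeros(100)), p)
        np.testing.assert_array_equal(ft.luminance_adjust(p, p), 0.0)

    def test_adjust_is_linear_and_exact(self, rng):
        a, b = rng.normal(size=(2, 50))
        l = rng.normal(size=50)
        lhs = ft.luminance_adjust(2.0 * a + 3.0 * b, 5.0 * l)
        rhs = 2.0 * ft.luminance_adjust(a, l) + 3.0 * ft.luminance_adjust(b, l)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_adjust_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ft.luminance_adjust(np.zeros(3), np.zeros(4))


class TestBlinks:
    def test_empty_window_rate_zero(self):
        assert ft.blink_rate(np.array([]), (0.0, 10.0)) == 0.0

    def test_three_onsets_in_window(self):
        assert ft.blink_rate(np.array([1.0, 2.0, 7.0]), (0.0, 7.5)) == pytest.approx(0.4)

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError):
            ft.blink_rate(np.array([1.0]), (5.0, 5.0))

    def test_timer_without_blinks_equals_elapsed_time(self):
        t = np.arange(0, 10, 1 / 60)
        timer, pre = ft.interblink_timer(np.array([]), t, window_start=0.0)
        np.testing.assert_allclose(timer, t)
        assert pre.all()

    def test_timer_resets_at_each_onset(self):
        t = np.arange(0, 10, 0.1)
        timer, pre = ft.interblink_timer(np.array([2.0, 6.0]), t)
        i59 = np.argmin(np.abs(t - 5.9))
        i60 = np.argmin(np.abs(t - 6.0))
        assert timer[i59] == pytest.approx(3.9)
        assert timer[i60] == pytest.approx(0.0)
        assert not pre[i59]

    def test_timer_never_decreases_except_across_resets(self, rng):
        t = np.arange(0, 30, 1 / 60)
        onsets = np.sort(rng.uniform(0, 30, 8))
        timer, _ = ft.interblink_timer(onsets, t)
        d = np.diff(timer)
        decreasing = d < -1e-12
        assert np.all(timer[1:][decreasing] <= 1 / 60 + 1e-9)


class TestRmssd:
    def test_constant_ibi_gives_zero(self):
        assert ft.rmssd(np.full(10, 0.8)) == 0.0

    def test_hand_computed_triplet(self):
        assert ft.rmssd(np.array([0.80, 0.85, 0.80])) == pytest.approx(0.05)

    def test_matches_direct_formula_oracle(self, rng):
        v = rng.uniform(0.6, 1.0, 50)
        want = np.sqrt(np.mean(np.diff(v) ** 2))  # independent direct formula
        assert ft.rmssd(v) == pytest.approx(want, abs=1e-12)

    def test_short_window_yields_missing(self):
        assert np.isnan(ft.rmssd(np.array([0.8, 0.9])))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        ibi=st.lists(
            st.floats(0.4, 1.5, allow_nan=False), min_size=3, max_size=40
        )
    )
    def test_arbitrary_ibi_vectors_match_direct_formula(self, ibi):
        v = np.asarray(ibi)
        want = np.sqrt(np.mean(np.diff(v) ** 2))
        assert ft.rmssd(v) == pytest.approx(want, abs=1e-12)

    def test_held_log_collapsed_to_beats_before_rmssd(self):
        held = np.array([0.8] * 8 + [0.85] * 9 + [0.8] * 8)
        assert ft.collapse_held_ibi(held).tolist() == [0.8, 0.85, 0.8]
        assert ft.rmssd(held, collapse=True) == pytest.approx(0.05)


class TestScl:
    def test_conversion_values(self):
        np.testing.assert_allclose(
            ft.scl_convert(np.array([1000.0, 500.0])), [1.0, 2.0]
        )

    def test_nonpositive_resistance_becomes_missing(self):
        out = ft.scl_convert(np.array([-5.0, 0.0, 100.0]))
        assert np.isnan(out[:2]).all() and out[2] == 10.0

    def test_round_trip_identity(self, rng):
        x = rng.uniform(0.5, 20.0, 30)  # µS
        np.testing.assert_allclose(ft.scl_convert(1000.0 / x), x, rtol=1e-12)

    def test_motionless_channels_mask_nothing(self):
        accel = np.tile([0.0, 0.0, 1.0], (100, 1))
        gyro = np.zeros((100, 3))
        assert not ft.movement_mask(accel, gyro, rate_hz=10.0).any()

    def test_single_spike_masks_dilated_window(self):
        accel = np.tile([0.0, 0.0, 1.0], (101, 1))
        accel[50, 0] = 0.8
        gyro = np.zeros((101, 3))
        mask = ft.movement_mask(accel, gyro, rate_hz=10.0, dilation_s=0.5)
        t = np.arange(101) / 10.0
        np.testing.assert_array_equal(mask, (t >= 4.5) & (t <= 5.5))

    def test_gyro_threshold_triggers_mask(self):
        accel = np.tile([0.0, 0.0, 1.0], (20, 1))
        gyro = np.zeros((20, 3))
        gyro[4, 1] = 120.0
        assert ft.movement_mask(accel, gyro, rate_hz=10.0, dilation_s=0.0)[4]


class TestDetrend:
    def test_exact_line_yields_zero_residuals(self):
        t = np.linspace(0, 10, 200)
        out = ft.detrend_linear(t, 3.0 * t - 7.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_line_plus_sinusoid_leaves_centered_sinusoid(self):
        t = np.linspace(0, 20, 1200)
        wave = np.sin(2 * np.pi * t)  # integer periods: orthogonal-ish to line
        out = ft.detrend_linear(t, 0.5 * t + 2.0 + wave)
        # the discrete grid leaves a small residual line-sinusoid overlap
        assert np.abs(out - (wave - wave.mean())).max() < 6e-2

    def test_residuals_have_zero_mean_and_slope(self, rng):
        t = np.linspace(0, 30, 500)
        out = ft.detrend_linear(t, rng.normal(size=500))
        assert abs(out.mean()) < 1e-9
        slope = np.polyfit(t, out, 1)[0]  # normal-equations oracle
        assert abs(slope) < 1e-9

    def test_matches_normal_equations_oracle(self, rng):
        t = np.linspace(0, 5, 100)
        v = rng.normal(size=100)
        n = t.size  # closed-form simple-regression oracle
        b = (n * (t * v).sum() - t.sum() * v.sum()) / (n * (t**2).sum() - t.sum() ** 2)
        a = v.mean() - b * t.mean()
        np.testing.assert_allclose(ft.detrend_linear(t, v), v - (a + b * t), atol=1e-9)

    def test_degenerate_time_axis_rejected(self):
        with pytest.raises(ValueError):
            ft.detrend_linear(np.zeros(10), np.arange(10.0))


class TestDisplacement:
    def test_hand_computed_example(self):
        out, flag = ft.displacement_from_start(np.array([100.0, 98.0, 97.0]))
        np.testing.assert_array_equal(out, [0.0, -2.0, -3.0])
        assert not flag

    def test_first_output_always_zero(self, rng):
        out, _ = ft.displacement_from_start(rng.normal(size=20))
        assert out[0] == 0.0

    def test_constant_series_gives_zeros(self):
        out, _ = ft.displacement_from_start(np.full(5, 7.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_missing_first_value_uses_first_available_and_flags(self):
        out, flag = ft.displacement_from_start(np.array([np.nan, 5.0, 7.0]))
        assert flag
        assert out[1] == 0.0 and out[2] == 2.0
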
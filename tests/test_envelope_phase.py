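"""Tests of smoothing, extremum detection, envelopes, and phase extraction."""

import numpy as np
import pytest

from scnwave.envelope_phase import (
    amplitude,
    build_envelopes,
    detect_extrema,
    enforce_alternation,
    extract_pixel,
    hilbert_phase,
    phase,
    smooth_series,
)
from scnwave.sync_metrics import wrap_phase

T24 = 24.0


def _ma_gain(period, dt, window):
    """Closed-form attenuation of a cosine by the centered moving average."""
    half = int(round(window / (2 * dt)))
    k = np.arange(-half, half + 1)
    return np.mean(np.cos(2 * np.pi * k * dt / period))


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        x = np.full(100, 3.5)
        np.testing.assert_allclose(smooth_series(x, 0.5), x)

    def test_cosine_attenuated_by_moving_average_gain(self):
        t = np.arange(0, 120, 0.5)
        x = np.cos(2 * np.pi * t / T24)
        xs = smooth_series(x, 0.5)
        g = _ma_gain(T24, 0.5, 6.0)
        interior = slice(13, -13)
        np.testing.assert_allclose(xs[interior], g * x[interior], atol=1e-12)

    def test_impulse_becomes_rectangular_bump(self):
        x = np.zeros(101)
        x[50] = 1.0
        xs = smooth_series(x, 0.5)
        width = 13  # 6 h window at 0.5 h sampling
        assert np.count_nonzero(xs) == width
        np.testing.assert_allclose(xs[50 - 6 : 50 + 7], 1.0 / width)

    def test_window_longer_than_trace_raises(self):
        with pytest.raises(ValueError):
            smooth_series(np.ones(5), 0.5, window=6.0)


class TestExtrema:
    def test_cosine_peak_and_trough_times(self):
        t = np.arange(0, 72.0001, 0.5)
        peaks, troughs = detect_extrema(np.cos(2 * np.pi * t / T24))
        assert sorted(t[troughs]) == pytest.approx([12, 36, 60], abs=0.5)
        # interior peaks plus the boundary extrema the window cuts off
        assert sorted(t[peaks]) == pytest.approx([0, 24, 48, 72], abs=0.5)

    def test_monotone_ramp_flags_non_oscillatory(self):
        t = np.arange(0, 80, 0.5)
        res = extract_pixel(t * 2.0 + 5.0, t)
        assert not res.oscillatory
        assert np.all(np.isnan(res.theta))

    def test_damped_cosine_matches_fine_grid_oracle(self):
        """Peak count preserved and peak times within one sample of the
        maxima of the smoothed damped cosine located on a 100x finer grid."""
        tau = 100.0
        t = np.arange(0, 120.0001, 0.5)
        xs = smooth_series(np.exp(-t / tau) * np.cos(2 * np.pi * t / T24), 0.5)
        peaks, _ = detect_extrema(xs, min_separation=19)
        tf = np.arange(0, 120.0001, 0.005)
        xf = smooth_series(np.exp(-tf / tau) * np.cos(2 * np.pi * tf / T24), 0.005)
        fine_peaks, _ = detect_extrema(xf, min_separation=1900)
        assert len(peaks) == len(fine_peaks)
        np.testing.assert_allclose(t[peaks], tf[fine_peaks], atol=0.5)

    def test_plateau_resolved_to_midpoint(self):
        x = np.array([0, 1, 2, 3, 3, 3, 2, 1, 0, 1, 2, 3, 2, 1, 0], dtype=float)
        peaks, troughs = detect_extrema(x, include_boundaries=False)
        assert 4 in peaks  # midpoint of the flat top at indices 3..5
        assert 8 in troughs

    def test_alternation_keeps_more_extreme_duplicate(self):
        xs = np.array([0, 5, 1, 7, 0, -3, 0], dtype=float)
        p, t = enforce_alternation(xs, np.array([1, 3]), np.array([5]))
        assert list(p) == [3] and list(t) == [5]


class TestEnvelopes:
    def setup_method(self):
        self.t = np.arange(0, 120.0001, 0.5)

    def test_pure_cosine_envelopes_are_constant(self):
        b, a = 100.0, 30.0
        xs = b + a * np.cos(2 * np.pi * self.t / T24)  # unsmoothed: exact anchors
        peaks, troughs = detect_extrema(xs)
        env = build_envelopes(self.t, xs, peaks, troughs)
        common = np.isfinite(env.h) & np.isfinite(env.l)
        np.testing.assert_allclose(env.h[common], b + a, atol=1e-2)
        np.testing.assert_allclose(env.l[common], b - a, atol=1e-2)
        np.testing.assert_allclose(amplitude(env)[common], a, atol=1e-2)

    def test_linearly_decaying_peaks_interpolate_linearly(self):
        times = np.arange(9, dtype=float)
        xs = np.array([0, 10, 0, 9, 0, 8, 0, 7, 0], dtype=float)
        env = build_envelopes(times, xs, np.array([1, 3, 5, 7]), np.array([2, 4, 6]))
        np.testing.assert_allclose(env.h[1:8], [10, 9.5, 9, 8.5, 8, 7.5, 7])

    def test_damped_envelope_tracks_exponential_within_chord_error(self):
        tau = 72.0
        a0 = 30.0
        x = a0 * np.exp(-self.t / tau) * np.cos(2 * np.pi * self.t / T24)
        res = extract_pixel(x + 100.0, self.t)
        assert res.oscillatory
        # compare A(t) to the closed-form envelope of the *smoothed* signal
        g = _ma_gain(T24, 0.5, 6.0)
        ok = np.isfinite(res.amplitude)
        ok &= (self.t > 24) & (self.t < 96)
        exact = g * a0 * np.exp(-self.t[ok] / tau)
        # linear interpolation overestimates a convex decaying envelope by
        # at most its one-period chord error
        chord = exact * (np.exp(T24 / tau) - 1 - T24 / tau)
        assert np.all(res.amplitude[ok] - exact < 1.05 * chord + 0.02 * a0)
        assert np.all(res.amplitude[ok] - exact > -0.05 * a0)


class TestPhase:
    def test_pure_cosine_phase_is_linear_and_zero_at_peaks(self):
        t = np.arange(0, 120.0001, 0.5)
        res = extract_pixel(100 + 30 * np.cos(2 * np.pi * t / T24), t)
        # exact on the interior (away from the shrinking-window ends,
        # whose envelope anchors are slightly attenuated)
        ok = np.isfinite(res.theta) & (t >= 24) & (t <= 96)
        d = res.theta[ok] - 2 * np.pi * t[ok] / T24
        np.testing.assert_allclose(d - d[0], 0.0, atol=1e-9)
        ok_all = np.isfinite(res.theta)
        d_all = res.theta[ok_all] - 2 * np.pi * t[ok_all] / T24
        np.testing.assert_allclose(d_all - d[0], 0.0, atol=5e-3)
        for tp in res.envelopes.peak_times:
            i = np.searchsorted(t, tp)
            if not np.isfinite(res.theta[i]):
                continue  # outside the common envelope domain
            assert res.theta[i] == pytest.approx(
                2 * np.pi * round(res.theta[i] / (2 * np.pi)), abs=1e-6
            )

    def test_phase_at_troughs_is_pi(self, damped_trace):
        t, x, _ = damped_trace
        res = extract_pixel(x, t)
        env = res.envelopes
        for tt in env.trough_times:
            i = np.searchsorted(t, tt)
            if np.isfinite(res.theta[i]):
                assert abs(wrap_phase(res.theta[i] - np.pi)) < 1e-6

    def test_theta_advances_two_pi_per_cycle(self, damped_trace):
        t, x, _ = damped_trace
        res = extract_pixel(x, t)
        idx = res.envelopes.peak_indices
        vals = res.theta[idx]
        vals = vals[np.isfinite(vals)]
        np.testing.assert_allclose(np.diff(vals), 2 * np.pi, atol=1e-6)

    def test_affine_intensity_invariance(self, damped_trace):
        t, x, _ = damped_trace
        r1 = extract_pixel(x, t)
        r2 = extract_pixel(3.7 * x + 50.0, t)
        ok = np.isfinite(r1.theta) & np.isfinite(r2.theta)
        np.testing.assert_allclose(r1.theta[ok], r2.theta[ok], atol=1e-9)
        ok = np.isfinite(r1.amplitude) & np.isfinite(r2.amplitude)
        np.testing.assert_allclose(3.7 * r1.amplitude[ok], r2.amplitude[ok], rtol=1e-9)

    def test_envelope_phase_agrees_with_hilbert(self, damped_trace):
        """The consistency check: both extractions give nearly the same
        phase on a damped oscillatory trace (circular RMS < 0.05 rad/2pi
        after discarding half a period at each end)."""
        t, x, _ = damped_trace
        res = extract_pixel(x, t)
        th_h, a_h = hilbert_phase(res.smoothed, res.envelopes)
        keep = np.isfinite(res.theta) & (t > t[0] + 12) & (t < t[-1] - 12)
        d = wrap_phase(res.theta[keep] - th_h[keep])
        # remove the arbitrary common origin before the circular RMS
        z = np.exp(1j * d)
        d0 = np.angle(z.mean())
        rms = np.sqrt(np.mean(wrap_phase(d - d0) ** 2))
        assert rms / (2 * np.pi) < 0.05

    def test_hilbert_amplitude_matches_envelope_amplitude(self, damped_trace):
        t, x, _ = damped_trace
        res = extract_pixel(x, t)
        _, a_h = hilbert_phase(res.smoothed, res.envelopes)
        keep = np.isfinite(res.amplitude) & (t > 24) & (t < 96)
        ratio = a_h[keep] / res.amplitude[keep]
        assert abs(np.median(ratio) - 1) < 0.05

    def test_white_noise_pixel_flagged_non_oscillatory(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 100, 0.5)
        res = extract_pixel(rng.normal(100, 1.0, t.size), t)
        # smoothed white noise has no prominent circadian-scale extrema
        assert not res.oscillatory
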
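"""Screening analytics: masks, trends, responsive-pixel selection, metrics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from voltkit.datamodel import Movie, PixelMask, StimulusEvent, StimulusProtocol, Trace
from voltkit.screening import (brightness_ratio, compute_snr,
                               detect_light_onset, detrend_divide,
                               estimate_background_and_mask, fit_trend,
                               photostability_metrics, process_spectra,
                               relative_response_increase, response_amplitude,
                               select_responsive_mask, weighted_brightness)


def three_term_curve(t):
    return 0.3 * np.exp(-2.0 * t) + 0.5 * np.exp(-0.2 * t) + 0.2 \
        + 0.1 * np.exp(-8.0 * t)


class TestBackgroundAndMask:
    def test_flat_background_with_bright_blobs(self, rng):
        img = np.full((5, 32, 32), 100.0) + rng.normal(0, 1, (5, 32, 32))
        blob = np.zeros((32, 32), dtype=bool)
        blob[5:12, 5:12] = True
        img[:, blob] = 1000.0
        bg, mask = estimate_background_and_mask(Movie(img, 100.0))
        assert bg == pytest.approx(100.0, abs=2.0)
        np.testing.assert_array_equal(mask.grid, blob)

    def test_uniform_frame_gives_empty_mask(self):
        movie = Movie(np.full((3, 8, 8), 50.0), 100.0)
        with pytest.warns(UserWarning, match="empty"):
            bg, mask = estimate_background_and_mask(movie)
        assert mask.n_pixels == 0
        assert bg == pytest.approx(50.0, abs=1.0)

    def test_saturated_pixels_excluded_from_mask(self, rng):
        img = np.full((5, 16, 16), 100.0) + rng.normal(0, 1, (5, 16, 16))
        img[:, 2:6, 2:6] = 900.0
        img[:, 3, 3] = 1000.0           # saturated
        movie = Movie(img, 100.0, saturation_level=1000.0)
        _, mask = estimate_background_and_mask(movie)
        assert not mask.grid[3, 3]
        assert mask.grid[2, 2]


class TestFitTrend:
    def test_noiseless_three_term_recovery(self):
        t = np.arange(2000) / 100.0
        tr = Trace(three_term_curve(t), 100.0)
        trend = fit_trend(tr, n_terms=3)
        np.testing.assert_allclose(trend.evaluate(t), tr.values, rtol=1e-4)

    def test_excluded_transients_do_not_bias_trend(self):
        t = np.arange(2000) / 100.0
        clean = three_term_curve(t)
        dirty = clean.copy()
        win = (t >= 5.0) & (t < 7.0)
        dirty[win] *= 0.6               # large transient inside the window
        tr_clean = fit_trend(Trace(clean, 100.0), n_terms=3)
        tr_dirty = fit_trend(Trace(dirty, 100.0),
                             exclude_windows=[(5.0, 7.0)], n_terms=3)
        np.testing.assert_allclose(tr_dirty.evaluate(t),
                                   tr_clean.evaluate(t), rtol=1e-3)

    def test_constant_trace_gives_flat_trend(self):
        t = np.arange(500) / 100.0
        trend = fit_trend(Trace(np.full(500, 3.0), 100.0), n_terms=3)
        np.testing.assert_allclose(trend.evaluate(t), 3.0, rtol=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_trend(Trace(np.ones(20), 100.0), n_terms=3)


class TestDetrendDivide:
    def test_data_equal_trend_gives_ones(self):
        t = np.arange(1000) / 100.0
        trend = fit_trend(Trace(three_term_curve(t), 100.0), n_terms=3)
        out = detrend_divide(Trace(trend.evaluate(t), 100.0), trend)
        np.testing.assert_allclose(out.values, 1.0, rtol=1e-12)

    def test_multiplicative_signal_recovered_exactly(self):
        t = np.arange(1000) / 100.0
        s = 0.05 * np.sin(2 * np.pi * 1.5 * t)
        trend = fit_trend(Trace(three_term_curve(t), 100.0), n_terms=3)
        data = Trace(trend.evaluate(t) * (1 + s), 100.0)
        out = detrend_divide(data, trend)
        np.testing.assert_allclose(out.values, 1 + s, rtol=1e-12)

    def test_movie_per_pixel_amplitudes(self):
        """Shared time constants, per-pixel gains fitted linearly."""
        t = np.arange(600) / 100.0
        base = 0.4 * np.exp(-1.0 * t) + 0.6 * np.exp(-0.05 * t)
        gains = np.array([[1.0, 2.0], [0.5, 3.0]])
        frames = base[:, None, None] * gains[None, :, :]
        movie = Movie(frames, 100.0)
        trend = fit_trend(Trace(frames.reshape(600, -1).sum(axis=1), 100.0),
                          n_terms=2)
        out = detrend_divide(movie, trend)
        np.testing.assert_allclose(out.frames, 1.0, rtol=1e-6)

    def test_nonpositive_trend_rejected(self):
        from voltkit.screening import ExpTrend
        trend = ExpTrend(n_terms=1, amplitudes=np.array([1.0]),
                         rates=np.array([-5.0]), offset=-0.5)
        with pytest.raises(ValueError):
            detrend_divide(Trace(np.ones(100), 100.0), trend)


def _brute_force_best_prefix(movie, initial, protocol, batch):
    """Oracle: evaluate every batch prefix of the correlation ranking."""
    flat = movie.frames.reshape(movie.n_frames, -1)
    idx = initial.indices()
    traces = flat[:, idx]
    overall = traces.sum(axis=1)
    corr = [np.corrcoef(traces[:, j], overall)[0, 1]
            for j in range(idx.size)]
    order = np.argsort(-np.asarray(corr), kind="stable")
    best = (-np.inf, None)
    n_batches = int(np.ceil(idx.size / batch))
    for k in range(1, n_batches + 1):
        sel = order[:k * batch]
        snr = compute_snr(traces[:, sel[sel < idx.size]].sum(axis=1),
                          movie.rate, protocol)
        if snr > best[0]:
            best = (snr, k)
    return best


class TestResponsiveMaskSelection:
    def _make_fov(self, n_resp=60, n_noise=80, seed=0):
        rng = np.random.default_rng(seed)
        n, rows, cols = 600, 12, 12
        t = np.arange(n) / 200.0
        proto = StimulusProtocol([StimulusEvent(onset=1.0, duration=0.002),
                                  StimulusEvent(onset=2.0, duration=0.002)])
        s = np.zeros(n)
        for ev in proto.events:
            m = t >= ev.onset
            s[m] -= 0.2 * np.exp(-(t[m] - ev.onset) / 0.05)
        frames = np.ones((n, rows * cols))
        pix = rng.permutation(rows * cols)
        resp, noise = pix[:n_resp], pix[n_resp:n_resp + n_noise]
        frames[:, resp] += s[:, None] + 0.002 * rng.standard_normal((n, n_resp))
        frames[:, noise] += 0.05 * rng.standard_normal((n, n_noise))
        movie = Movie(frames.reshape(n, rows, cols), 200.0)
        grid = np.zeros(rows * cols, dtype=bool)
        grid[pix[:n_resp + n_noise]] = True
        initial = PixelMask(grid.reshape(rows, cols))
        resp_grid = np.zeros(rows * cols, dtype=bool)
        resp_grid[resp] = True
        return movie, initial, proto, PixelMask(resp_grid.reshape(rows, cols))

    def test_matches_brute_force_prefix_oracle(self):
        movie, initial, proto, resp_mask = self._make_fov()
        secondary, snr = select_responsive_mask(movie, initial, proto,
                                                batch=20)
        oracle_snr, oracle_k = _brute_force_best_prefix(movie, initial,
                                                        proto, 20)
        assert snr == pytest.approx(oracle_snr, rel=1e-9)
        assert secondary.n_pixels == oracle_k * 20

    def test_noise_pixels_rejected(self):
        movie, initial, proto, resp_mask = self._make_fov()
        secondary, snr = select_responsive_mask(movie, initial, proto,
                                                batch=20)
        # selected pixels should be (mostly) the responsive set
        overlap = (secondary.grid & resp_mask.grid).sum()
        assert overlap / resp_mask.n_pixels == pytest.approx(1.0, abs=0.05)
        _, snr_full = select_responsive_mask(movie, initial, proto,
                                             batch=10**6)
        assert snr >= snr_full

    def test_mask_smaller_than_batch_returned_whole(self):
        movie, initial, proto, _ = self._make_fov(n_resp=30, n_noise=30)
        secondary, _ = select_responsive_mask(movie, initial, proto,
                                              batch=200)
        np.testing.assert_array_equal(secondary.grid, initial.grid)

    def test_identical_pixels_tie_to_fewest_batches(self):
        n, rows, cols = 600, 8, 8
        t = np.arange(n) / 200.0
        proto = StimulusProtocol([StimulusEvent(onset=1.0, duration=0.002)])
        s = np.where(t >= 1.0, -0.2 * np.exp(-(t - 1.0) / 0.05), 0.0)
        frames = np.tile((1 + s)[:, None], (1, rows * cols))
        movie = Movie(frames.reshape(n, rows, cols), 200.0)
        initial = PixelMask(np.ones((rows, cols), dtype=bool))
        secondary, _ = select_responsive_mask(movie, initial, proto, batch=16)
        assert secondary.n_pixels == 16          # one batch


class TestResponseAmplitude:
    def test_square_pulse_amplitude(self):
        n = 1000
        t = np.arange(n) / 1000.0
        v = np.ones(n)
        v[(t >= 0.5) & (t < 0.6)] = 0.8
        proto = StimulusProtocol([StimulusEvent(onset=0.5, duration=0.1)])
        resp = response_amplitude(Trace(v, 1000.0), proto,
                                  response_window=0.05)
        assert resp[0].amplitude == pytest.approx(-0.20, abs=1e-12)

    def test_equal_events_give_equal_amplitudes(self):
        n = 3000
        t = np.arange(n) / 1000.0
        v = np.ones(n)
        for onset in (0.5, 1.5):
            m = t >= onset
            v[m] -= 0.1 * np.exp(-(t[m] - onset) / 0.01)
            v[m] += 0.1 * np.exp(-(t[m] - onset) / 0.002)
        proto = StimulusProtocol([StimulusEvent(onset=0.5, duration=0.002),
                                  StimulusEvent(onset=1.5, duration=0.002)])
        resp = response_amplitude(Trace(v, 1000.0), proto)
        assert resp[0].amplitude == pytest.approx(resp[1].amplitude, rel=1e-6)

    def test_truncated_event_window_raises(self):
        proto = StimulusProtocol([StimulusEvent(onset=0.95, duration=0.2)])
        with pytest.raises(ValueError, match="truncated"):
            response_amplitude(Trace(np.ones(1000), 1000.0), proto)

    def test_width_at_fraction_of_peak(self):
        # triangular dip of half-width 50 ms: width at 30% spans where
        # deviation >= 0.3*peak, i.e. 70% of the full triangle base
        n = 2000
        t = np.arange(n) / 1000.0
        v = np.ones(n)
        tri = np.clip(1 - np.abs(t - 1.0) / 0.05, 0, None)
        v -= 0.2 * tri
        proto = StimulusProtocol([StimulusEvent(onset=0.95, duration=0.1)])
        resp = response_amplitude(Trace(v, 1000.0), proto,
                                  response_window=0.05, width_frac=0.3)
        assert resp[0].width_s == pytest.approx(0.07, rel=0.05)


class TestBrightness:
    def test_uniform_ratio(self):
        mask = PixelMask(np.ones((4, 4), dtype=bool))
        assert brightness_ratio(np.full((4, 4), 200.0),
                                np.full((4, 4), 100.0), mask) == 2.0

    def test_homogeneity_in_green(self, rng):
        mask = PixelMask(rng.random((6, 6)) > 0.4)
        g = rng.random((6, 6)) + 1
        r = rng.random((6, 6)) + 1
        base = brightness_ratio(g, r, mask)
        assert brightness_ratio(3.0 * g, r, mask) == pytest.approx(3 * base)

    def test_multi_fov_pixel_weighting(self):
        assert weighted_brightness([2.0, 4.0], [100, 300]) == \
            pytest.approx(3.5)

    def test_relative_increase_formula(self):
        assert relative_response_increase(-20.0, -10.0) == pytest.approx(100.0)


class TestPhotostability:
    def test_constant_trace_budget_equals_duration(self):
        n = 1200
        tr = Trace(np.ones(n), 10.0)     # 120 s
        budget, half = photostability_metrics(tr)
        assert budget == pytest.approx((n - 1) / 10.0, rel=1e-9)
        assert half is None

    def test_pure_exponential_half_life_closed_form(self):
        t = np.arange(3000) / 100.0      # 30 s
        tr = Trace(np.exp(-t / 10.0), 100.0)
        budget, half = photostability_metrics(tr)
        assert half == pytest.approx(10.0 * np.log(2), rel=1e-3)

    def test_noisy_three_term_vs_root_finding_oracle(self, rng):
        t = np.arange(6000) / 100.0      # 60 s
        curve = 0.5 * np.exp(-t / 3.0) + 0.5 * np.exp(-t / 40.0)
        noisy = curve + 0.005 * rng.standard_normal(t.size)
        noisy[0] = 1.0
        _, half = photostability_metrics(Trace(noisy, 100.0))
        oracle = brentq(lambda x: 0.5 * np.exp(-x / 3.0)
                        + 0.5 * np.exp(-x / 40.0) - 0.5, 0.01, 60.0)
        assert half == pytest.approx(oracle, rel=0.02)

    def test_unnormalized_trace_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            photostability_metrics(Trace(np.full(100, 2.0), 10.0))

    def test_budget_monotone_under_pointwise_smaller_trace(self):
        t = np.arange(1000) / 100.0
        hi = np.exp(-t / 20.0)
        lo = hi * np.exp(-t / 50.0)      # pointwise smaller, still 1 at t=0
        b_hi, _ = photostability_metrics(Trace(hi, 100.0))
        b_lo, _ = photostability_metrics(Trace(lo, 100.0))
        assert b_lo <= b_hi


class TestSpectraProcessing:
    wl = np.arange(350.0, 536.0)

    def _gauss(self, center, width=18.0, amp=1.0):
        return amp * np.exp(-0.5 * ((self.wl - center) / width) ** 2)

    def test_clean_gaussian_peak_wavelength(self):
        scans = [self._gauss(487.0, amp=500.0) + 20.0 for _ in range(3)]
        blanks = [np.full(self.wl.size, 20.0)] * 2
        res = process_spectra(self.wl, scans, blanks)
        assert res.peak_wavelength == pytest.approx(487.0, abs=1.0)
        assert res.spectrum.max() == 1.0

    def test_scan_with_high_edge_efficiency_excluded(self):
        good = self._gauss(487.0, amp=500.0)
        bad = good + 0.15 * 500.0        # 15% residual at both edges
        res = process_spectra(self.wl, [good, good, bad], [])
        assert res.n_used == 2
        assert res.n_excluded == 1

    def test_all_scans_excluded_raises(self):
        bad = self._gauss(487.0, amp=1.0) + 0.5
        with pytest.raises(ValueError, match="excluded"):
            process_spectra(self.wl, [bad], [])


class TestLightOnset:
    def test_dark_then_bright(self):
        frames = np.concatenate([np.full((5, 4, 4), 1.0),
                                 np.full((15, 4, 4), 500.0)])
        assert detect_light_onset(Movie(frames, 100.0)) == 5

    def test_gradual_ramp_earliest_above_threshold(self):
        frames = np.ones((20, 2, 2))
        frames[10] *= 300.0              # half-way frame
        frames[11:] *= 500.0
        assert detect_light_onset(Movie(frames, 100.0),
                                  threshold_frac=0.5) == 10

    def test_already_bright_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="bright"):
            idx = detect_light_onset(Movie(np.full((10, 2, 2), 500.0), 100.0))
        assert idx == 0
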
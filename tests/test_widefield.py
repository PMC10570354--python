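"""Dual-channel preprocessing: ΔF/F₀, band filters, sequential regression."""

import numpy as np
import pytest

from voltkit.datamodel import (DualChannelRecording, Movie, RunConfig, Trace)
from voltkit.synth import MovieSimConfig, bleach_curve, gen_dual_channel_movie
from voltkit.widefield import (apply_bleach_template, band_filter,
                               compute_dff, estimate_bleach_template,
                               regress_step, run_pipeline,
                               subtract_background)


def _recording(frames_g, frames_r, rate=200.0):
    return DualChannelRecording(green=Movie(frames_g, rate, channel="green"),
                                red=Movie(frames_r, rate, channel="red"))


class TestBackgroundSubtraction:
    def test_plateau_maps_to_zero(self):
        g = np.full((10, 4, 4), 130.0)
        rec = _recording(g, g + 20.0)
        out = subtract_background(rec, 130.0, 150.0)
        np.testing.assert_array_equal(out.green.frames, 0.0)
        np.testing.assert_array_equal(out.red.frames, 0.0)

    def test_zero_background_is_identity(self):
        g = np.random.default_rng(0).random((5, 3, 3)) + 1
        rec = _recording(g, g)
        out = subtract_background(rec, 0.0, 0.0)
        np.testing.assert_array_equal(out.green.frames, g)

    def test_constant_map_matches_scalar_path(self):
        g = np.random.default_rng(1).random((5, 3, 3)) + 2
        rec = _recording(g, g)
        out_scalar = subtract_background(rec, 1.5, 1.5)
        out_map = subtract_background(rec, np.full((3, 3), 1.5),
                                      np.full((3, 3), 1.5))
        np.testing.assert_array_equal(out_scalar.green.frames,
                                      out_map.green.frames)

    def test_shape_mismatch_rejected(self):
        rec = _recording(np.ones((5, 3, 3)), np.ones((5, 3, 3)))
        with pytest.raises(ValueError, match="shape"):
            subtract_background(rec, np.ones((4, 4)), 0.0)


class TestBleachTemplate:
    def test_known_two_term_recovered_within_two_percent(self, rng):
        rate, n = 200.0, 4096
        t = np.arange(n) / rate
        true = 80.0 * np.exp(-t / 2.0) + 1920.0 * np.exp(-t * 5e-4)
        traces = []
        for _ in range(8):
            sig = 0.01 * rng.standard_normal(n)
            traces.append(Trace(true * (1 + sig), rate))
        tpl = estimate_bleach_template(traces)
        fitted = tpl.evaluate(t)
        np.testing.assert_allclose(fitted, true, rtol=0.02)

    def test_flat_traces_have_negligible_decay(self):
        traces = [Trace(np.full(1000, 500.0), 200.0)]
        tpl = estimate_bleach_template(traces)
        t = np.arange(1000) / 200.0
        np.testing.assert_allclose(tpl.evaluate(t), 500.0, rtol=1e-6)

    def test_single_trace_is_valid_input(self):
        t = np.arange(800) / 200.0
        tpl = estimate_bleach_template([Trace(100 * np.exp(-t / 3), 200.0)])
        assert tpl.n_traces_used == 1

    def test_short_traces_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            estimate_bleach_template([Trace(np.ones(100), 200.0)])

    def test_divisive_application_flattens_decay(self):
        rate, n = 200.0, 2000
        t = np.arange(n) / rate
        tr = Trace(1000.0 * bleach_curve(t, (0.05, -0.4, 0.95, -1e-3)), rate)
        tpl = estimate_bleach_template([tr])
        out = apply_bleach_template(tr, tpl)
        np.testing.assert_allclose(out.values, out.values[0], rtol=1e-3)


class TestComputeDff:
    def test_closed_form_values(self):
        n = 1000
        v = np.full(n, 100.0)
        v[800] = 80.0
        v[900] = 200.0
        out = compute_dff(Trace(v, 200.0), baseline_window=(2.0, 2.5))
        assert out.values[800] == pytest.approx(-0.20)
        assert out.values[900] == pytest.approx(1.0)

    def test_constant_trace_is_all_zeros(self):
        out = compute_dff(Trace(np.full(1000, 7.0), 200.0))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_nonpositive_baseline_rejected(self):
        v = np.full(1000, -1.0)
        with pytest.raises(ValueError, match="F0"):
            compute_dff(Trace(v, 200.0))


class TestBandFilter:
    rate = 200.0
    n = 4096

    def _sine(self, freq):
        t = np.arange(self.n) / self.rate
        return Trace(np.sin(2 * np.pi * freq * t), self.rate)

    def test_in_band_tone_preserved(self):
        out = band_filter(self._sine(5.0), (4.0, 20.0))
        amp = out.values[500:-500].std() * np.sqrt(2)
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_tone_attenuated_40db(self):
        out = band_filter(self._sine(5.0), (10.0, 30.0))
        assert np.sqrt(np.mean(out.values ** 2)) < 10 ** (-40 / 20)

    def test_dc_preserved_by_lowpass(self):
        tr = Trace(np.full(self.n, 3.5), self.rate)
        out = band_filter(tr, (None, 1.0))
        np.testing.assert_allclose(out.values, 3.5, atol=1e-9)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            band_filter(self._sine(5.0), (10.0, 120.0))


class TestRegressStep:
    def test_orthogonal_construction_recovers_signal(self):
        rate, n = 200.0, 4000
        t = np.arange(n) / rate
        s = np.sin(2 * np.pi * 3 * t)
        r = np.sin(2 * np.pi * 7 * t)     # orthogonal over the record
        g = Trace(s + 0.7 * r, rate)
        out, step = regress_step(g, Trace(r, rate))
        assert step.beta == pytest.approx(0.7, abs=1e-6)
        np.testing.assert_allclose(out.values, s, atol=1e-6)

    def test_uncorrelated_reference_leaves_signal(self, rng):
        rate, n = 200.0, 4000
        g = Trace(np.sin(2 * np.pi * 3 * np.arange(n) / rate), rate)
        r = Trace(rng.standard_normal(n), rate)
        out, step = regress_step(g, r)
        assert abs(step.beta) < 0.05
        np.testing.assert_allclose(out.values, g.values, atol=0.1)

    def test_residual_orthogonal_to_regressor(self, rng):
        g = Trace(rng.standard_normal(2000), 200.0)
        r = Trace(rng.standard_normal(2000), 200.0)
        out, _ = regress_step(g, r)
        rel = abs(np.dot(out.values, r.values)) / (
            np.linalg.norm(out.values) * np.linalg.norm(r.values))
        assert rel < 1e-10

    def test_idempotence(self, rng):
        g = Trace(rng.standard_normal(2000), 200.0)
        r = Trace(rng.standard_normal(2000), 200.0)
        once, _ = regress_step(g, r)
        twice, step2 = regress_step(once, r)
        assert abs(step2.beta) < 1e-12
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_variance_never_increases(self, rng):
        for _ in range(5):
            g = Trace(rng.standard_normal(1000), 200.0)
            r = Trace(rng.standard_normal(1000) + 0.3 * g.values, 200.0)
            out, _ = regress_step(g, r)
            assert np.sum(out.values ** 2) <= np.sum(g.values ** 2) + 1e-12

    def test_zero_variance_reference_rejected(self):
        g = Trace(np.random.default_rng(0).random(100), 200.0)
        with pytest.raises(ValueError, match="variance"):
            regress_step(g, Trace(np.zeros(100), 200.0))

    def test_intercept_absorbs_offset(self, rng):
        g = Trace(rng.standard_normal(1000) + 5.0, 200.0)
        r = Trace(rng.standard_normal(1000), 200.0)
        out, step = regress_step(g, r, with_intercept=True)
        assert step.intercept == pytest.approx(5.0, abs=0.2)
        assert abs(out.values.mean()) < 1e-12


class TestRunPipeline:
    def test_artifact_free_input_passes_through(self):
        """No artifacts, no noise: output equals clean ΔF/F₀."""
        cfg = MovieSimConfig.anesthetized(
            shape=(8, 8), duration=10.24, heartbeat_amp=0.0,
            slow_hemo_amp=0.0, shared_noise_sd=0.0, independent_noise_sd=0.0)
        # bleach template from independent trials, so this trial's slow
        # voltage cannot leak into it (mirrors the corpus-based template)
        tmpl_traces = []
        for s in (20, 21, 22, 23):
            rec_t, _ = gen_dual_channel_movie(cfg, seed=s)
            sub = Movie(rec_t.green.frames - cfg.background_level, cfg.rate)
            tmpl_traces += [sub.roi_trace(2, 2, 2), sub.roi_trace(4, 4, 2)]
        tpl = estimate_bleach_template(tmpl_traces)
        rec, gt = gen_dual_channel_movie(cfg, seed=2)
        run_cfg = RunConfig(mode="anesthetized")
        res = run_pipeline(rec, run_cfg, rois=[(2, 2)],
                           bg_green=cfg.background_level,
                           bg_red=cfg.background_level,
                           bleach_template=tpl)
        clean = gt.clean_dff(2, 2, 2)
        out = res.corrected[:, 0]
        # compare up to the ΔF/F baseline-window offset
        r = np.corrcoef(out, clean)[0, 1]
        assert r > 0.99

    def test_awake_mode_uses_published_bands(self):
        cfg = MovieSimConfig.awake(shape=(8, 8), duration=10.24)
        rec, _ = gen_dual_channel_movie(cfg, seed=1)
        res = run_pipeline(rec, RunConfig(mode="awake"), rois=[(2, 2)],
                           bg_green=cfg.background_level,
                           bg_red=cfg.background_level)
        bands = [s.band for s in res.steps[0]]
        assert bands == [(10.0, 30.0), (1.0, 10.0), (None, 1.0)]

    def test_pixelwise_and_roi_agree_for_identical_pixels(self):
        rate, n = 200.0, 2048
        t = np.arange(n) / rate
        g1 = 1000.0 * (1 + 0.05 * np.sin(2 * np.pi * 5 * t))
        r1 = 800.0 * (1 + 0.065 * np.sin(2 * np.pi * 5 * t))
        g = np.tile(g1[:, None, None], (1, 2, 2))
        r = np.tile(r1[:, None, None], (1, 2, 2))
        rec = _recording(g, r)
        cfg = RunConfig(mode="anesthetized", roi_size=2)
        roi = run_pipeline(rec, cfg)
        pix = run_pipeline(rec, cfg, pixelwise=True)
        np.testing.assert_allclose(roi.corrected[:, 0],
                                   pix.corrected[:, 0], atol=1e-9)

    def test_stage_errors_are_labeled(self):
        rec = _recording(np.zeros((1024, 4, 4)), np.zeros((1024, 4, 4)))
        with pytest.raises(RuntimeError, match="stage"):
            run_pipeline(rec, RunConfig(mode="anesthetized"))
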
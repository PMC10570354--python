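# voltkit

Analysis toolkit for widefield imaging with genetically encoded voltage
indicators (GEVIs).

Fluorescent voltage indicators report membrane potential as small, fast
fractional fluorescence changes (ΔF/F₀). Turning raw camera counts into
voltage signals requires a chain of quantitative steps that are easy to get
subtly wrong: photobleaching must be removed divisively, heartbeat and
slower hemodynamic artifacts must be regressed out using a co-acquired
reference fluorophore, indicator kinetics must be summarized by
exponential time constants fitted together with the response onset, and
spike-reporting fidelity must be scored against ground truth with a
precision/recall framework. `voltkit` implements this chain as a tested
library plus CLI, for experimenters analyzing screening plates,
patch-clamp fluorescence recordings, and in vivo widefield movies — and it
ships seeded synthetic-data generators so every stage can be validated
end to end without any data download.

## What is implemented

- **Screening analytics** (`voltkit.screening`): histogram background
  estimation and foreground masks, three-term exponential trend removal by
  division, SNR-maximizing selection of responsive pixels in
  correlation-ranked batches of 200, per-event response amplitudes and
  widths, green/red brightness ratios, photostability (photon budget and
  half-life), excitation/emission spectra processing with the ±10 %
  edge-efficiency exclusion rule, and excitation-light onset detection.
- **Kinetics** (`voltkit.kinetics`): mono/dual exponential-with-onset
  fitting of step responses,

      F(t) = c + k·e^{(t−t0)λ}                      (t > t0)
      F(t) = c + k                                  (t ≤ t0)

  (dual form adds `k2·e^{(t−t0)λ2}`), with the onset `t0` fitted jointly
  with the other coefficients; τ = −1000/λ in ms, fraction fast
  = 100·|k_fast|/(|k_fast|+|k_slow|); block-mean downsampling to 20 kHz and
  baseline bleach correction.
- **Spike scoring** (`voltkit.spikes`): command-voltage peak detection
  (prominence ≥ 10 mV, separation ≥ 1 ms), fluorescence spike detection
  (60-Hz high-pass, 2σ threshold from a 500-ms baseline), and greedy
  time-bin matching with Precision, Recall and F1 = 2PR/(P+R).
- **Widefield pipeline** (`voltkit.widefield`): background subtraction →
  two-term-exponential bleach-template detrending → ΔF/F₀ (baseline
  2–2.5 s) → 70-Hz lowpass → sequential band-filtered OLS regression of
  the reference channel (10–30 / 1–10 / 0–1 Hz awake, 4–20 / 1–4 / 0–1 Hz
  anesthetized, configurable).
- **Spectral analyses** (`voltkit.spectral`): Welch PSD,
  stimulation-frequency power-difference maps (40/60 Hz tagging),
  magnitude-squared coherence, LFP correlation maps with a modal
  best-channel helper, and derangement-shuffled trial controls.
- **Synthetic data** (`voltkit.synth`): seeded generators for dual-channel
  movies (heartbeat, slow hemodynamics, bi-exponential bleach, shared
  illumination noise, hidden 1/f² voltage signal with per-pixel ground
  truth), onset-exponential step traces, spike trains, and screening
  fields of view under electric field stimulation.

## Worked example

Recover the kinetics of a fast indicator from a noisy synthetic step
response, then clean a synthetic anesthetized widefield trial:

```python
import numpy as np
from voltkit import (MovieSimConfig, RunConfig, fit_exp_onset,
                     gen_dual_channel_movie, gen_step_trace,
                     psd_peak_frequency, run_pipeline, compute_dff, Trace)

# dual-exponential depolarization: tau_fast 0.54 ms, tau_slow 10.3 ms,
# fraction fast 89.3%, 1% noise at 20 kHz
params = dict(c=0.75, k=0.223, k2=0.027, lam=-1000/0.54, lam2=-1000/10.3,
              t0=0.1)
trace = gen_step_trace(params, rate=20000, duration=1.1, noise_sd=0.01,
                       seed=3)
fit = fit_exp_onset(trace, model_order=2, nominal_onset=0.1)
print(fit.summary())

cfg = MovieSimConfig.anesthetized()
rec, truth = gen_dual_channel_movie(cfg, seed=1)
roi = rec.green.roi_trace(10, 10, 2)
dff = compute_dff(Trace(roi.values - cfg.background_level, cfg.rate))
print("uncorrected peak: %.1f Hz"
      % psd_peak_frequency(dff, fmin=2.0, refine="centroid"))
res = run_pipeline(rec, RunConfig(mode="anesthetized"), rois=[(10, 10)],
                   bg_green=cfg.background_level,
                   bg_red=cfg.background_level)
r = np.corrcoef(res.corrected[:, 0], truth.clean_dff(10, 10, 2))[0, 1]
print("corr with hidden voltage: %.3f" % r)
```

Output:

```
Onset-exponential fit (order 2)
  n = 22000, RSS = 2.17612
  plateau c = 0.750038
  onset t0 = 99.99 ms
  tau_fast = 0.5327 ms
  tau_slow = 8.942 ms
  fraction fast = 87.45 %
uncorrected peak: 4.9 Hz
corr with hidden voltage: 0.921
```

The fitted fast time constant (0.53 ms against a generating 0.54 ms) and
fraction fast (87.5 % against 89.3 %) are single-replicate estimates; the
acceptance script below reports medians over 50 replicates. The
uncorrected ROI trace is dominated by the ~5-Hz heartbeat artifact; after
the three-band reference regression the output correlates at r ≈ 0.9 with
the hidden voltage signal (r ≈ 0.97 when the bleach template is estimated
from independent trials, as the pipeline is designed to be used).

A CLI wraps the same functionality: `voltkit synth movie`, `voltkit
screen`, `voltkit kinetics fit`, `voltkit spikes score`, `voltkit
preprocess`, `voltkit spectral coherence|powermap|corrmap`.

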
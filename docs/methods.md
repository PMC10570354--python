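# Methods

This note documents the models, parameter choices, and numerical decisions
behind `voltkit`, and what the synthetic-data generators do and do not
emulate.

## Signal model

A widefield dual-channel recording is modeled as a green (indicator)
channel and a red (reference) channel sharing one clock. After background
subtraction the green channel is, per pixel,

    G(t) = G₀ · B(t) · (1 + v(t)·g_v + a(t)·g_a + ε(t)),

where `B(t)` is a two-term exponential photobleaching factor, `v(t)` the
voltage-dependent fractional fluorescence change, `a(t)` the hemodynamic
and motion artifacts, and `ε(t)` noise. The red channel carries the same
artifacts and the same illumination noise but no voltage term and no
apparent bleaching. Because bleaching and signals compose
multiplicatively, trend removal is divisive throughout the toolkit:
dividing by a fitted trend (or bleach template) converts the record to the
`1 + signal` scale exactly when the data follow the fitted family.

## Kinetics: the onset-exponential model

Step responses are fitted with a piecewise model that is constant before a
fitted onset time `t0` and relaxes exponentially after it:

    F(t) = c + k·e^{(t−t0)λ}            t > t0        (mono)
    F(t) = c + k                        t ≤ t0

with the dual form adding `k2·e^{(t−t0)λ2}` and baseline `c + k + k2`.
`c` is the plateau, `k`/`k2` are component amplitudes, and `λ`/`λ2 < 0`
are the negative reciprocal time constants; the model is continuous at
`t0`. Reported quantities: `τ_i = −1000/λ_i` (ms), components labeled so
`τ_fast ≤ τ_slow`, and fraction fast `= 100·|k_fast|/(|k_fast|+|k_slow|)`
— an amplitude-ratio convention chosen because it yields percentages that
sum to 100 across components.

**Fitting.** For fixed `(t0, λ, λ2)` the model is linear in
`(c, k, k2)`, so the fitter uses variable projection: amplitudes are
solved by linear least squares inside a bounded nonlinear search over the
onset and the log-rates (log-parameterization keeps rates negative and
spans decades). The search is multi-started over an 11-point onset grid
(±10 ms around the nominal onset) crossed with log-spaced time-constant
starts, first on decimated samples (~4000 points) to rank starts cheaply,
then polished at full resolution from the best start. The onset grid
exists because the indicator function `t > t0` makes the objective only
piecewise smooth in `t0`. Noiseless model data are recovered to machine
precision; fits whose total amplitude falls below 3× the residual noise
level are flagged degenerate and report no time constants.

**Model order.** When not fixed by the caller, the order is chosen by
small-sample-corrected AIC with an amplitude floor: the dual model is
accepted only if it improves AICc *and* both components exceed 3× the
residual noise sd; otherwise the mono model is kept (parsimony).

**Preprocessing.** Raw high-rate traces are block-mean decimated to
20 kHz (exact DC preservation) and bleach-corrected by dividing out a
three-term exponential fitted on baseline (holding-potential) windows
only.

## Screening analytics

- **Background**: mode of a 256-bin histogram over the lower half of the
  intensity range of the mean first frames — robust to bright foreground.
- **Initial mask**: pixels above background + 5 robust (MAD-based)
  standard deviations; pixels reaching the saturation level are excluded.
  The 5σ threshold is configurable; it reproduces the intent of a
  predefined-threshold mask without hard-coded camera constants.
- **Trend removal**: three-term exponential plus constant offset, rates
  constrained negative, variable projection with 8 log-spaced multi-starts
  spanning time constants from span/100 to 10×span; stimulation windows
  are excluded from the fit. For movies, the shared fitted rates are kept
  and per-pixel amplitudes re-fitted linearly before divisive detrending.
- **Responsive-pixel selection**: pixels ranked by decreasing Pearson
  correlation with the mask-summed detrended trace, grouped in batches of
  200, accumulated from the top; the returned mask is the batch prefix
  with maximal summed-trace SNR. SNR (the underlying method leaves it
  unspecified) is defined as the peak absolute stimulus-locked deviation
  from the event-free baseline mean divided by the event-free baseline
  standard deviation. Ties within floating-point rounding keep the
  smaller prefix. On small fields this selection is verified against
  brute-force evaluation of every prefix.
- **Photostability**: photon budget is the trapezoidal area under the
  brightness-normalized trace (seconds); half-life is the first crossing
  of 0.5 by a fitted three-term exponential (bisection-refined), or none.
- **Spectra**: each scan is corrected by the mean blank, normalized to its
  own peak, and discarded if the normalized efficiency at either end of
  the wavelength range exceeds 10 % in magnitude (improper
  autofluorescence correction); survivors are averaged, the average
  re-normalized to peak 1, and the peak wavelength reported as the mean of
  per-scan argmax wavelengths.

## Spike detection and scoring

Command-voltage spikes: local maxima with prominence ≥ 10 mV separated by
≥ 1 ms. Fluorescence spikes: the trace is polarity-rectified (this
indicator family is negative-going; polarity is an explicit parameter),
zero-phase high-passed at 60 Hz (4th-order Butterworth, forward-backward),
and peaks above 2× the noise σ are kept, with σ the standard deviation of
a 500-ms spike-free baseline.

Matching walks the ground truth first-to-last; each truth spike takes the
nearest unmatched detection within ± the time bin (tie → the earlier
detection) and the pair is removed. The bin defaults to the minimum
inter-spike interval of the truth train. Precision = TP/(TP+FP), Recall =
TP/(TP+FN), F1 = 2PR/(P+R). Degenerate conventions (never reached by real
protocols, fixed for totality): both sides empty ⇒ P = R = F1 = 1
(perfect silence); one side empty ⇒ the undefined ratio is 0 and F1 = 0.
When truth spikes are separated by at least twice the bin, the greedy
pass provably attains the maximum-cardinality matching; the tests verify
this against a brute-force bipartite matcher on instances of up to 12
spikes. Scoring windows (e.g. 0.25–0.75 s of a waveform) are half-open
`[start, stop)`.

## Widefield correction pipeline

Ordered stages: (1) background subtraction per channel (scalar or
per-pixel map); (2) divisive detrending of the green channel by a bleach
template — each contributing trace is lowpassed at 0.5 Hz, averaged, and
fitted to a two-term exponential with offset; (3) ΔF/F₀ on both channels
with F₀ the mean over the 2–2.5-s baseline window; (4) zero-phase 70-Hz
lowpass on the green ΔF/F₀; (5) one ordinary-least-squares regression
step per configured band, high→low: the reference ΔF/F₀ is band-filtered,
scaled by the fitted β, and subtracted. Default bands are 10–30, 1–10,
0–1 Hz (awake), 4–20, 1–4, 0–1 Hz (anesthetized), and a five-band variant
for awake LFP sessions; the number of bands is configurable. Regression
is scale-only except in the ≤1-Hz band, where an optional intercept
(default on) absorbs DC leakage. Each step is an orthogonal projection:
residuals are orthogonal to the regressor, applying a step twice changes
nothing, and output variance never exceeds input variance. Analyses run
per 2×2-pixel ROI by default, or per pixel.

**Filter choice.** The regression band filters are zero-phase
frequency-domain filters with exactly unit passband gain and raised-cosine
transitions of 0.3 Hz (endpoint-line removal suppresses wrap-around
leakage; the line is restored for pure lowpass bands, where it is passband
content). A low-order IIR band filter is unsuitable here: the
anesthetized ~5-Hz heartbeat sits against the 4-Hz edge of its band,
where a 4th-order zero-phase Butterworth retains only ~0.9 gain — the
regressor is then missing part of the in-band artifact, which no scale
coefficient can recover, and the transition-band mismatch biases β upward.
Butterworth filters are retained where edges are far from the signals of
interest: the 70-Hz lowpass, the 60-Hz spike high-pass, the 0.5-Hz bleach
lowpass, and LFP conditioning.

**Bleach template in practice.** The template should be estimated from
traces of many independent trials, so that slow physiological activity
(shared across pixels within one trial) averages out; estimating it from
a single trial's own traces lets sub-0.5-Hz signal leak into the template
and measurably attenuates slow signal content. `run_pipeline` accepts a
precomputed template for exactly this reason and self-estimates only as a
fallback.

## Spectral analyses

Welch PSDs use Hann windows with 50 % overlap. Power-difference maps
compute, per ROI, a spectrogram (Hann, 0.5-s segments, 75 % overlap —
configurable and echoed in the result), take the bin nearest the target
frequency (40 or 60 Hz), average segments inside the stimulation and
baseline windows, and map the difference; a trial-averaging helper is
provided. Magnitude-squared coherence uses 2-s Welch segments with 50 %
overlap and is clipped to [0, 1]. LFP conditioning follows the order
invert → anti-aliased downsample to the imaging rate → 70-Hz lowpass →
optional 60-Hz notch. Correlation maps are per-ROI Pearson coefficients
against the conditioned LFP; the best-channel helper returns the modal
argmax channel across ROIs. Shuffled controls pair imaging and LFP trials
by seeded random derangements (no trial keeps its own partner; 1000
shuffles by default). The heartbeat-peak readout refines the Welch argmax
bin by a power-weighted centroid within ±0.75 Hz, the appropriate center
estimate for a frequency-jittered oscillation.

## Synthetic data: what it emulates, and what it does not

The movie generator reproduces the statistical structure the analyses
rely on: a 200-Hz dual-camera recording of 20.48-s trials; bi-exponential
green-channel bleaching reaching ~95 % at trial end (A₁ = 0.04,
λ₁ = −0.5 s⁻¹, A₂ = 0.96, λ₂ = −5·10⁻⁴ s⁻¹); a heartbeat artifact at 5 Hz
(anesthetized) or 12 Hz (awake) modeled as an amplitude-modulated
sinusoid with bounded ±5 % random-walk frequency jitter — deliberately
not a pure tone, so it cannot be removed by a trivial notch; slow
hemodynamics as 0.1–1-Hz band noise; illumination noise identical in both
channels and band-limited below 10 Hz (light-source fluctuations are
slow; their being shared is what lets the reference regression correct
them); independent Gaussian sensor noise per channel (Poisson optional —
the regression math is noise-model agnostic); and a hidden voltage signal
with a 1/f² spectrum over 0.3–15 Hz, matching the steep low-frequency
weighting of cortical voltage and field-potential spectra. Artifact and
noise amplitudes are not published quantities; the defaults — heartbeat
2 %, slow hemodynamics 1 %, shared illumination noise 0.5 %, independent
sensor noise 0.3 %, voltage sd 1 % of mean fluorescence — are fixed,
field-plausible choices recorded in `MovieSimConfig`. The spatial grid
defaults to 32×32 rather than the camera's 100×100; all per-ROI analyses
are spatially local, so the grid size does not change the statistics
under test. Per-channel artifact gains (red/green ≈ 1.3) share one
spatial pattern, making single-coefficient regression exact in principle.

Not emulated: optical point-spread functions, vascular geometry, skull
optics, motion that requires registration (the pipeline's regression
handles only fluorescence-coupled artifacts), photon-transfer curves of
specific cameras, and nonstationary heart rates beyond the jitter model.
Passing tests therefore demonstrate the correctness and self-consistency
of the algorithms under the stated signal model — not robustness to every
feature of real preparations.

The step-trace generator evaluates the onset-exponential model exactly
and adds Gaussian noise; the screening generator stamps disk-shaped cells
with EFS-locked transients (four 1-ms pulses at 0.5-s period from t = 1 s,
then a 100-Hz train of ten 2.5-ms pulses) and returns the responsive
pixel set as ground truth.

## Problem sizes and reproducibility

Kinetics recovery experiments use 50 replicates of 1.1-s traces at
20 kHz with 1 % noise (seeds derived from a single base seed); widefield
experiments use six 20.48-s trials at 200 Hz on a 32×32 grid with a
bleach template estimated from six additional independent trials. All
generators are deterministic given (config, seed): identical inputs give
bit-identical outputs. `scripts/acceptance.py` recomputes the headline
numbers from scratch at these sizes in about two minutes.

## Known limitations

- The exact SNR formula, initial-mask thresholds, and model-selection
  rule of the original screening/kinetics procedures are unpublished;
  the conventions above are documented, configurable stand-ins.
- Whether the overall-trace correlation used for pixel ranking should
  exclude stimulation windows is unspecified; all samples are included by
  default.
- The ≤1-Hz regression step has few degrees of freedom over a 20-s trial
  (~40), so a few percent of slow signal variance is unavoidably removed
  by chance correlation with the reference; longer records shrink this
  loss.
- Regressed ΔF/F₀ is returned as-is; it is not re-referenced to a
  post-regression baseline for display.
- Divisive vs subtractive bleach-template removal is selectable
  (`bleach_mode`); divisive is the default, consistent with the
  multiplicative signal model.
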
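"""Dual-channel widefield preprocessing: from raw counts to corrected ΔF/F₀.

The pipeline removes non-voltage fluorescence from the indicator (green)
channel using the co-acquired reference (red) channel:

1. background subtraction on both channels;
2. divisive photobleaching detrending of the green channel with a two-term
   exponential template estimated from 0.5-Hz-lowpassed traces;
3. ΔF/F₀ on both channels, with F₀ the mean over a 2–2.5 s baseline window;
4. 70-Hz lowpass on the green ΔF/F₀;
5. sequential ordinary-least-squares regression: the reference ΔF/F₀ is
   band-filtered (high→low: 10–30, 1–10, 0–1 Hz awake; 4–20, 1–4, 0–1 Hz
   anesthetized), scaled, and subtracted from the green trace one band at a
   time, removing heartbeat and slower hemodynamic/motion artifacts that
   are shared between channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._filters import apply_zero_phase
from .datamodel import DualChannelRecording, Movie, RunConfig, Trace
from .screening import fit_trend


@dataclass
class RegressionStep:
    """One band-regression step: g_{n+1} = g_n − β·r_band (− α)."""

    band: tuple[float | None, float]
    beta: float
    intercept: float | None = None
    input_label: str = "g"
    output_label: str = "g'"


@dataclass
class BleachTemplate:
    """Two-term exponential photobleaching template (plus constant offset)."""

    a1: float
    lam1: float
    a2: float
    lam2: float
    offset: float
    n_traces_used: int = 0
    lowpass_cutoff: float = 0.5

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.offset + self.a1 * np.exp(self.lam1 * t)
                + self.a2 * np.exp(self.lam2 * t))


def subtract_background(rec: DualChannelRecording,
                        bg_green: float | np.ndarray,
                        bg_red: float | np.ndarray) -> DualChannelRecording:
    """Subtract per-channel background (scalar or per-pixel map).

    Output frames are floating point; negative values are permitted but a
    warning is raised when more than 1% of samples go negative.
    """
    out = {}
    for name, movie, bg in (("green", rec.green, bg_green),
                            ("red", rec.red, bg_red)):
        bg = np.asarray(bg, dtype=float)
        if bg.ndim == 2 and bg.shape != movie.shape:
            raise ValueError(f"{name} background map shape mismatch")
        frames = movie.frames.astype(float) - bg
        frac_neg = float((frames < 0).mean())
        if frac_neg > 0.01:
            warnings.warn(f"{name}: {frac_neg:.1%} of samples negative "
                          "after background subtraction", stacklevel=2)
        out[name] = Movie(frames, movie.rate,
                          saturation_level=movie.saturation_level,
                          channel=movie.channel)
    return DualChannelRecording(green=out["green"], red=out["red"],
                                trial_id=rec.trial_id,
                                metadata=dict(rec.metadata))


def estimate_bleach_template(traces: list[Trace],
                             lowpass_cutoff: float = 0.5) -> BleachTemplate:
    """Fit the mean fast-photobleaching decay of a set of traces.

    Each trace is lowpass filtered at ``lowpass_cutoff`` Hz, the filtered
    traces are averaged, and the average is fitted to a two-term
    exponential model (with offset).
    """
    if not traces:
        raise ValueError("need at least one trace")
    rate = traces[0].rate
    n = traces[0].n
    if any(tr.rate != rate or tr.n != n for tr in traces):
        raise ValueError("traces must share length and rate")
    if n / rate < 2.0:
        raise ValueError("traces shorter than 2 s")
    mean = np.mean([apply_zero_phase(tr.values, (None, lowpass_cutoff), rate)
                    for tr in traces], axis=0)
    trend = fit_trend(Trace(mean, rate), n_terms=2)
    order = np.argsort(trend.rates)          # faster (more negative) first
    amps = trend.amplitudes[order]
    lams = trend.rates[order]
    tpl = BleachTemplate(a1=float(amps[0]), lam1=float(lams[0]),
                         a2=float(amps[1]), lam2=float(lams[1]),
                         offset=trend.offset, n_traces_used=len(traces),
                         lowpass_cutoff=lowpass_cutoff)
    t = np.arange(n) / rate
    if np.any(tpl.evaluate(t) <= 0):
        raise ValueError("bleach template not positive over the trial")
    return tpl


def apply_bleach_template(trace: Trace, template: BleachTemplate,
                          mode: str = "divide") -> Trace:
    """Remove the bleach template from a trace (divisive by default).

    Divisive: the trace is divided by the template normalized to its
    initial value.  Subtractive: the template's decay (scaled to the
    trace's mean level) is subtracted.
    """
    t = trace.times - trace.t0_offset
    tpl = template.evaluate(t)
    if mode == "divide":
        return trace.with_values(trace.values / (tpl / tpl[0]))
    if mode == "subtract":
        scale = float(np.mean(trace.values)) / float(np.mean(tpl))
        return trace.with_values(trace.values - scale * (tpl - tpl[0]))
    raise ValueError("mode must be 'divide' or 'subtract'")


def compute_dff(trace: Trace,
                baseline_window: tuple[float, float] = (2.0, 2.5)) -> Trace:
    """ΔF/F₀ with F₀ the mean fluorescence over ``baseline_window`` (s)."""
    t = trace.times
    sel = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not sel.any():
        raise ValueError("baseline window outside the record")
    f0 = float(np.mean(trace.values[sel]))
    if f0 <= 0:
        raise ValueError("baseline F0 must be positive")
    return Trace((trace.values - f0) / f0, trace.rate,
                 t0_offset=trace.t0_offset, units="dF/F",
                 polarity=trace.polarity)


def band_filter(trace: Trace, band: tuple[float | None, float],
                transition: float = 0.3) -> Trace:
    """Zero-phase band-limited copy of a trace.

    ``band=(low, high)``; ``low=None`` gives a pure lowpass.  The filter is
    a frequency-domain design with unit passband gain and raised-cosine
    transitions of ``transition`` Hz: a regressor that kept less than unit
    gain inside its own band (as a low-order IIR filter would near the
    edges) could never fully remove an artifact sitting near a band edge,
    such as the anesthetized ~5-Hz heartbeat against the 4-Hz edge.
    """
    from ._filters import sharp_band_filter

    low, high = band
    if high >= trace.rate / 2:
        raise ValueError("band high edge at/above Nyquist")
    return trace.with_values(sharp_band_filter(trace.values, (low, high),
                                               trace.rate,
                                               transition=transition))


def regress_step(signal_dff: Trace, ref_band: Trace,
                 with_intercept: bool = False,
                 band: tuple[float | None, float] | None = None,
                 labels: tuple[str, str] = ("g", "g'")
                 ) -> tuple[Trace, RegressionStep]:
    """Scale-and-subtract one band-filtered reference via OLS.

    Finds ``β`` (and optionally an intercept ``α``) minimizing
    ``‖g − β·r − α‖²`` and returns ``g − β·r − α``; the residual is
    orthogonal to the regressor (and to the constant when the intercept is
    fitted).
    """
    if signal_dff.n != ref_band.n or signal_dff.rate != ref_band.rate:
        raise ValueError("signal and reference must share length and rate")
    g = signal_dff.values
    r = ref_band.values
    if float(np.var(r)) == 0:
        raise ValueError("reference band has zero variance")
    if with_intercept:
        a = np.column_stack([r, np.ones_like(r)])
        coef, *_ = np.linalg.lstsq(a, g, rcond=None)
        beta, alpha = float(coef[0]), float(coef[1])
        out = g - beta * r - alpha
    else:
        beta = float(np.dot(g, r) / np.dot(r, r))
        alpha = None
        out = g - beta * r
    step = RegressionStep(band=band if band is not None else (None, np.inf),
                          beta=beta, intercept=alpha,
                          input_label=labels[0], output_label=labels[1])
    return signal_dff.with_values(out), step


@dataclass
class PipelineResult:
    """Corrected ΔF/F₀ traces and the regression steps that produced them."""

    roi_origins: list[tuple[int, int]]
    corrected: np.ndarray                     # (n_frames, n_rois)
    steps: list[list[RegressionStep]]
    rate: float
    roi_size: int
    grid_shape: tuple[int, int] | None = None
    bleach_template: BleachTemplate | None = None
    config: RunConfig | None = None
    reference_dff: np.ndarray | None = None   # (n_frames, n_rois)
    uncorrected: np.ndarray | None = None     # green ΔF/F before regression

    @property
    def n_rois(self) -> int:
        return len(self.roi_origins)

    def trace(self, i: int) -> Trace:
        return Trace(self.corrected[:, i], self.rate, units="dF/F")

    def trace_at(self, row: int, col: int) -> Trace:
        i = self.roi_origins.index((row, col))
        return self.trace(i)

    def to_movie(self) -> Movie:
        """Corrected traces reassembled on the ROI grid (tiled runs only)."""
        if self.grid_shape is None:
            raise ValueError("pipeline was not run on a tiled ROI grid")
        nr, nc = self.grid_shape
        frames = self.corrected.reshape(-1, nr, nc)
        return Movie(frames, self.rate, channel="green")


def run_pipeline(rec: DualChannelRecording, cfg: RunConfig,
                 rois: list[tuple[int, int]] | None = None,
                 pixelwise: bool = False,
                 bg_green: float | np.ndarray = 0.0,
                 bg_red: float | np.ndarray = 0.0,
                 bleach_template: BleachTemplate | None = None,
                 bleach_mode: str = "divide",
                 intercept_below_1hz: bool = True) -> PipelineResult:
    """Run the full dual-channel correction pipeline.

    Stages (in order): background subtraction → green bleach-template
    divisive detrend → ΔF/F₀ on both channels → 70-Hz lowpass on green →
    one OLS regression step per configured band, high→low.  Works per ROI
    (default: non-overlapping ``cfg.roi_size`` blocks tiling the frame, or
    an explicit list of block origins) or per pixel.  Deterministic given
    its inputs.

    Regression is scale-only except for the ≤1-Hz lowpass band, where an
    intercept absorbs DC leakage (disable with ``intercept_below_1hz``).
    """
    cfg.validate_for(rec.rate, rec.n_frames / rec.rate)
    rec = subtract_background(rec, bg_green, bg_red)

    size = 1 if pixelwise else cfg.roi_size
    rows, cols = rec.green.shape
    if rois is None:
        origins = [(r, c) for r in range(0, rows - size + 1, size)
                   for c in range(0, cols - size + 1, size)]
        grid_shape = (len(range(0, rows - size + 1, size)),
                      len(range(0, cols - size + 1, size)))
    else:
        origins = list(rois)
        grid_shape = None

    def _stage(label: str, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{label}' failed: {exc}") \
                from exc

    green_rois = [rec.green.roi_trace(r, c, size) for r, c in origins]
    red_rois = [rec.red.roi_trace(r, c, size) for r, c in origins]

    if bleach_template is None:
        bleach_template = _stage("bleach-template", estimate_bleach_template,
                                 green_rois)

    n = rec.n_frames
    corrected = np.empty((n, len(origins)))
    uncorrected = np.empty((n, len(origins)))
    ref_dff = np.empty((n, len(origins)))
    all_steps: list[list[RegressionStep]] = []
    for i, (g_tr, r_tr) in enumerate(zip(green_rois, red_rois)):
        g_db = _stage("bleach-detrend", apply_bleach_template, g_tr,
                      bleach_template, bleach_mode)
        g = _stage("dff-green", compute_dff, g_db, cfg.baseline_window)
        r = _stage("dff-red", compute_dff, r_tr, cfg.baseline_window)
        g = _stage("lowpass-green", band_filter, g,
                   (None, cfg.lowpass_cutoff))
        uncorrected[:, i] = g.values
        ref_dff[:, i] = r.values
        steps: list[RegressionStep] = []
        for j, band in enumerate(cfg.band_edges):
            r_band = _stage(f"band-filter-{band}", band_filter, r, band)
            use_icpt = intercept_below_1hz and band[0] is None
            if float(np.var(r_band.values)) <= 1e-24:
                # a silent reference band has nothing to regress out
                steps.append(RegressionStep(band=band, beta=0.0,
                                            input_label=f"g{j + 1}",
                                            output_label=f"g{j + 2}"))
                continue
            g, step = _stage(f"regress-{band}", regress_step, g, r_band,
                             use_icpt, band,
                             (f"g{j + 1}", f"g{j + 2}"))
            steps.append(step)
        corrected[:, i] = g.values
        all_steps.append(steps)

    return PipelineResult(roi_origins=origins, corrected=corrected,
                          steps=all_steps, rate=rec.rate, roi_size=size,
                          grid_shape=grid_shape,
                          bleach_template=bleach_template, config=cfg,
                          reference_dff=ref_dff, uncorrected=uncorrected)
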
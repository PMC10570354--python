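"""High-throughput screening analytics for indicator fields of view.

Implements the screening chain used to rank indicator variants: histogram
background estimation and foreground masking, three-term exponential
photobleaching trends removed by division, SNR-maximizing selection of
responsive pixels in correlation-ranked batches, per-event response
amplitudes and widths, green/red brightness ratios, photostability metrics
(photon budget and half-life), excitation/emission spectra processing, and
excitation-light onset detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .datamodel import Movie, PixelMask, StimulusProtocol, Trace


@dataclass
class ExpTrend:
    """Multi-term exponential trend ``offset + Σ A_i exp(λ_i t)`` (λ_i < 0)."""

    n_terms: int
    amplitudes: np.ndarray
    rates: np.ndarray
    offset: float
    fit_window_mask: np.ndarray | None = None
    degenerate: bool = False

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.offset)
        for a, lam in zip(self.amplitudes, self.rates):
            out += a * np.exp(lam * t)
        return out


@dataclass
class EventResponse:
    """Per-event response: signed peak ΔF/F and width at a peak fraction."""

    onset: float
    amplitude: float
    width_s: float | None
    peak_time: float


@dataclass
class SpectrumResult:
    wavelengths: np.ndarray
    spectrum: np.ndarray
    peak_wavelength: float
    n_used: int
    n_excluded: int


@dataclass
class ScreeningMetrics:
    """Summary of a screening field of view."""

    response_amplitudes: list[float]
    brightness_gr: float
    snr: float
    initial_mask: PixelMask
    secondary_mask: PixelMask
    background_green: float
    photon_budget: float | None = None
    half_life: float | None = None
    responses: list[EventResponse] = field(default_factory=list)


def estimate_background_and_mask(movie: Movie, n_frames: int = 10,
                                 saturation_level: float | None = None,
                                 threshold_mult: float = 5.0
                                 ) -> tuple[float, PixelMask]:
    """Histogram background level and foreground mask from the first frames.

    The background is the mode of a 256-bin intensity histogram restricted
    to the lower half of the intensity range (robust to bright foreground).
    The mask keeps pixels more than ``threshold_mult`` robust (MAD-based)
    standard deviations above background; pixels reaching the saturation
    level in any of the first frames are excluded.
    """
    if movie.n_frames < 1:
        raise ValueError("need at least one frame")
    sat = saturation_level if saturation_level is not None \
        else movie.saturation_level
    first = movie.frames[:min(n_frames, movie.n_frames)].astype(float)
    img = first.mean(axis=0)
    saturated = (first >= sat).any(axis=0)
    if saturated.all():
        raise ValueError("all pixels saturated")

    lo, hi = float(img.min()), float(img.max())
    half = lo + 0.5 * (hi - lo) if hi > lo else hi + 1.0
    low_px = img[img <= half]
    counts, edges = np.histogram(low_px, bins=256)
    mode_bin = int(np.argmax(counts))
    background = 0.5 * (edges[mode_bin] + edges[mode_bin + 1])

    mad = np.median(np.abs(low_px - background))
    robust_sd = 1.4826 * mad
    thresh = background + threshold_mult * robust_sd
    grid = (img > thresh) & ~saturated
    if not grid.any():
        warnings.warn("empty foreground mask", stacklevel=2)
    return float(background), PixelMask(grid)


def _exclusion_mask(trace: Trace,
                    exclude_windows: list[tuple[float, float]] | None
                    ) -> np.ndarray:
    mask = np.zeros(trace.n, dtype=bool)
    if exclude_windows:
        t = trace.times
        for a, b in exclude_windows:
            mask |= (t >= a) & (t < b)
    return mask


def fit_trend(trace: Trace,
              exclude_windows: list[tuple[float, float]] | None = None,
              n_terms: int = 3, exclude_mask: np.ndarray | None = None,
              n_starts: int = 8) -> ExpTrend:
    """Least-squares multi-term exponential trend with a constant offset.

    Samples inside ``exclude_windows`` (e.g. stimulation periods) are left
    out of the fit.  Rates are constrained negative; amplitudes and offset
    are solved linearly for each candidate rate set (variable projection)
    while the rates are refined from ``n_starts`` log-spaced initializations
    spanning the record; the best fit by residual sum of squares wins.
    """
    if not 1 <= n_terms <= 3:
        raise ValueError("n_terms must be 1-3")
    if exclude_mask is None:
        exclude_mask = _exclusion_mask(trace, exclude_windows)
    keep = ~exclude_mask
    if keep.sum() < 10 * n_terms:
        raise ValueError("fewer than 10×n_terms samples retained")
    t = trace.times[keep]
    f = trace.values[keep]
    span = max(t[-1] - t[0], 1e-9)

    def _solve(lams: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = np.column_stack([np.ones_like(t)]
                            + [np.exp(lam * t) for lam in lams])
        coef, *_ = np.linalg.lstsq(a, f, rcond=None)
        return coef, f - a @ coef

    def residual(x: np.ndarray) -> np.ndarray:
        return _solve(-np.exp(x))[1]

    # log-spaced rate starts: time constants from span/100 to 10*span
    base_taus = np.geomspace(span / 100, 10 * span, n_starts)
    best: tuple[float, np.ndarray] | None = None
    for i in range(n_starts):
        taus = base_taus[(np.arange(n_terms) * max(n_starts // n_terms, 1)
                          + i) % n_starts]
        x0 = np.log(1.0 / taus)
        try:
            sol = least_squares(residual, x0, max_nfev=100,
                                bounds=(np.log(1 / (100 * span)),
                                        np.log(1e6)))
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return ExpTrend(n_terms=n_terms, amplitudes=np.zeros(n_terms),
                        rates=-np.ones(n_terms), offset=float(np.mean(f)),
                        fit_window_mask=keep, degenerate=True)
    lams = -np.exp(best[1])
    coef, _ = _solve(lams)
    return ExpTrend(n_terms=n_terms, amplitudes=coef[1:], rates=lams,
                    offset=float(coef[0]), fit_window_mask=keep)


def detrend_divide(data: Trace | Movie, trend: ExpTrend,
                   mask: PixelMask | None = None) -> Trace | Movie:
    """Remove a fitted trend by division.

    For a trace the output is ``data(t) / trend(t)``; detrending the trend
    itself gives 1 everywhere.  For a movie, the trend's shared time
    constants are kept and per-pixel amplitudes (and offset) are re-fitted
    by linear least squares before each pixel is divided by its own trend.
    With a ``mask``, only the selected pixels are detrended (background
    pixels carry no meaningful trend); the rest are set to 1.
    """
    if isinstance(data, Trace):
        tr = trend.evaluate(data.times)
        if np.any(tr <= 0):
            raise ValueError("trend not positive over the record")
        return data.with_values(data.values / tr)
    if isinstance(data, Movie):
        t = np.arange(data.n_frames) / data.rate
        basis = np.column_stack([np.ones_like(t)]
                                + [np.exp(lam * t) for lam in trend.rates])
        flat = data.frames.reshape(data.n_frames, -1).astype(float)
        if mask is not None:
            if mask.grid.shape != data.shape:
                raise ValueError("mask shape does not match movie")
            cols = mask.indices()
            flat = flat[:, cols]
        keep = trend.fit_window_mask
        if keep is not None and keep.size == data.n_frames:
            coef, *_ = np.linalg.lstsq(basis[keep], flat[keep], rcond=None)
        else:
            coef, *_ = np.linalg.lstsq(basis, flat, rcond=None)
        per_pixel_trend = basis @ coef
        if np.any(per_pixel_trend <= 0):
            raise ValueError("per-pixel trend not positive over the record")
        detr = flat / per_pixel_trend
        if mask is not None:
            out = np.ones((data.n_frames, data.shape[0] * data.shape[1]))
            out[:, cols] = detr
            out = out.reshape(data.frames.shape)
        else:
            out = detr.reshape(data.frames.shape)
        return Movie(out, data.rate, saturation_level=data.saturation_level,
                     channel=data.channel)
    raise TypeError("detrend_divide expects a Trace or Movie")


def compute_snr(values: np.ndarray, rate: float, protocol: StimulusProtocol,
                response_window: float = 0.3) -> float:
    """Stimulus SNR of a detrended summed trace.

    Defined as the peak absolute deviation from the event-free baseline
    mean, over all protocol events (each searched from its onset to
    ``duration + response_window`` after it), divided by the baseline
    standard deviation outside event windows.
    """
    n = values.size
    t = np.arange(n) / rate
    in_event = np.zeros(n, dtype=bool)
    for ev in protocol.events:
        in_event |= (t >= ev.onset) & (t < ev.onset + ev.duration
                                       + response_window)
    if in_event.all() or not in_event.any():
        return 0.0
    base = values[~in_event]
    mu, sd = float(np.mean(base)), float(np.std(base))
    if sd == 0:
        return np.inf
    return float(np.max(np.abs(values[in_event] - mu)) / sd)


def select_responsive_mask(movie_detr: Movie, initial: PixelMask,
                           protocol: StimulusProtocol, batch: int = 200,
                           response_window: float = 0.3
                           ) -> tuple[PixelMask, float]:
    """Keep the correlation-ranked pixel batches that maximize stimulus SNR.

    Pixels of the initial mask are ranked by decreasing Pearson correlation
    of their detrended trace with the mask-summed detrended trace, grouped
    in batches of ``batch`` pixels, and batches are accumulated from the
    top; the returned secondary mask is the batch prefix whose summed-trace
    SNR is maximal (ties resolved toward fewer batches).
    """
    if initial.n_pixels == 0:
        raise ValueError("initial mask is empty")
    if len(protocol) < 1:
        raise ValueError("protocol needs at least one event")
    flat = movie_detr.frames.reshape(movie_detr.n_frames, -1)
    idx = initial.indices()
    traces = flat[:, idx].astype(float)
    overall = traces.sum(axis=1)

    ov = overall - overall.mean()
    px = traces - traces.mean(axis=0)
    denom = np.linalg.norm(px, axis=0) * np.linalg.norm(ov)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, px.T @ ov / np.where(denom > 0, denom, 1),
                        -np.inf)
    order = np.argsort(-corr, kind="stable")

    n_batches = int(np.ceil(idx.size / batch))
    best_snr, best_k = -np.inf, 1
    cum = np.zeros(movie_detr.n_frames)
    for kb in range(n_batches):
        sel = order[kb * batch:(kb + 1) * batch]
        cum = cum + traces[:, sel].sum(axis=1)
        snr = compute_snr(cum, movie_detr.rate, protocol,
                          response_window=response_window)
        # ties (within float rounding) keep the smaller prefix
        if snr > best_snr * (1 + 1e-9) or (best_snr == -np.inf
                                           and not np.isnan(snr)):
            best_snr, best_k = snr, kb + 1
    chosen = order[:best_k * batch]
    grid = np.zeros(flat.shape[1], dtype=bool)
    grid[idx[chosen[chosen < idx.size]]] = True
    return PixelMask(grid.reshape(movie_detr.shape)), float(best_snr)


def response_amplitude(trace: Trace, protocol: StimulusProtocol,
                       baseline_window: float = 0.2,
                       response_window: float = 0.3,
                       width_frac: float = 0.3) -> list[EventResponse]:
    """Per-event signed peak ΔF/F relative to the local pre-event baseline.

    For each protocol event the baseline is the mean over
    ``baseline_window`` seconds before onset; the response is the extreme
    deviation (signed by its actual direction) within the window from onset
    to ``duration + response_window`` after it, normalized by the baseline.
    The response width is measured at ``width_frac`` of the peak deviation
    (default 30%).
    """
    t = trace.times
    out: list[EventResponse] = []
    for ev in protocol.events:
        end = ev.onset + ev.duration + response_window
        if end > t[-1] + 0.5 / trace.rate:
            raise ValueError(f"event window at {ev.onset}s truncated by "
                             "record end")
        base_sel = (t >= ev.onset - baseline_window) & (t < ev.onset)
        if not base_sel.any():
            raise ValueError(f"no baseline samples before event at {ev.onset}s")
        f0 = float(np.mean(trace.values[base_sel]))
        if f0 == 0:
            raise ValueError("zero pre-event baseline")
        win_sel = (t >= ev.onset) & (t < end)
        dev = trace.values[win_sel] - f0
        i_peak = int(np.argmax(np.abs(dev)))
        amp = float(dev[i_peak] / f0)
        # width at width_frac of peak: contiguous run around the peak
        thresh = width_frac * abs(dev[i_peak])
        above = np.abs(dev) >= thresh if thresh > 0 else np.zeros_like(dev,
                                                                       bool)
        width = None
        if thresh > 0:
            left = i_peak
            while left > 0 and above[left - 1]:
                left -= 1
            right = i_peak
            while right < dev.size - 1 and above[right + 1]:
                right += 1
            width = (right - left + 1) / trace.rate
        out.append(EventResponse(onset=ev.onset, amplitude=amp, width_s=width,
                                 peak_time=float(t[win_sel][i_peak])))
    return out


def brightness_ratio(green_frame: np.ndarray, red_frame: np.ndarray,
                     mask: PixelMask) -> float:
    """Mean green over mean red fluorescence within a mask (G/R score).

    Frames must be background-subtracted.
    """
    if mask.n_pixels == 0:
        raise ValueError("empty mask")
    g = float(np.mean(np.asarray(green_frame, float)[mask.grid]))
    r = float(np.mean(np.asarray(red_frame, float)[mask.grid]))
    if r <= 0:
        raise ValueError("red-channel mean is not positive")
    return g / r


def weighted_brightness(ratios: np.ndarray, pixel_counts: np.ndarray) -> float:
    """Multi-FOV G/R score weighted by secondary-mask pixel counts."""
    ratios = np.asarray(ratios, float)
    w = np.asarray(pixel_counts, float)
    if w.sum() <= 0:
        raise ValueError("no pixels to weight by")
    return float(np.sum(ratios * w) / np.sum(w))


def relative_response_increase(a: float, b: float) -> float:
    """Percent increase of response magnitude |a| over |b|."""
    if b == 0:
        raise ValueError("reference response is zero")
    return (abs(a) / abs(b) - 1.0) * 100.0


def photostability_metrics(norm_trace: Trace, n_terms: int = 3,
                           norm_tol: float = 0.05
                           ) -> tuple[float, float | None]:
    """Photon budget and half-life of a brightness-normalized trace.

    The photon budget is the trapezoidal area (seconds) under the trace,
    which must be normalized to 1 at its first sample.  The half-life is
    the first time the fitted multi-term exponential reaches 0.5, or None
    if never reached within the record.
    """
    v = norm_trace.values
    if abs(v[0] - 1.0) > norm_tol:
        raise ValueError("trace is not normalized to 1 at t=0")
    t = norm_trace.times - norm_trace.t0_offset
    budget = float(np.trapezoid(v, t))

    trend = fit_trend(Trace(v, norm_trace.rate), n_terms=n_terms)
    if trend.degenerate:
        return budget, None
    fitted = trend.evaluate(t)
    below = fitted <= 0.5
    if not below.any():
        return budget, None
    i = int(np.argmax(below))
    if i == 0:
        return budget, 0.0
    half = brentq(lambda x: trend.evaluate(np.array([x]))[0] - 0.5,
                  t[i - 1], t[i])
    return budget, float(half)


def process_spectra(wavelengths: np.ndarray, scans: list[np.ndarray],
                    blanks: list[np.ndarray],
                    edge_tolerance: float = 0.10) -> SpectrumResult:
    """Blank-subtract, peak-normalize, filter, and average raw spectra.

    Each scan is corrected by subtracting the mean blank (autofluorescence)
    at each wavelength and normalized to its own peak.  Scans whose
    normalized efficiency at either end of the wavelength range (e.g. 350
    or 535 nm for excitation) exceeds ``edge_tolerance`` in magnitude are
    excluded (improper autofluorescence correction).  The surviving scans
    are averaged and the average re-normalized to a peak of exactly 1; the
    peak wavelength is the mean of the per-scan argmax wavelengths.
    """
    wl = np.asarray(wavelengths, dtype=float)
    blank = np.mean([np.asarray(b, float) for b in blanks], axis=0) \
        if blanks else np.zeros_like(wl)
    kept, peaks = [], []
    n_excluded = 0
    for scan in scans:
        s = np.asarray(scan, float) - blank
        peak = np.max(np.abs(s))
        if peak == 0:
            n_excluded += 1
            continue
        s = s / s[int(np.argmax(np.abs(s)))]
        if abs(s[0]) > edge_tolerance or abs(s[-1]) > edge_tolerance:
            n_excluded += 1
            continue
        kept.append(s)
        peaks.append(wl[int(np.argmax(s))])
    if not kept:
        raise ValueError("all scans excluded")
    avg = np.mean(kept, axis=0)
    avg = avg / avg[int(np.argmax(avg))]
    return SpectrumResult(wavelengths=wl, spectrum=avg,
                          peak_wavelength=float(np.mean(peaks)),
                          n_used=len(kept), n_excluded=n_excluded)


def detect_light_onset(movie: Movie, threshold_frac: float = 0.5) -> int:
    """First frame whose mean intensity crosses a fraction of steady state.

    The steady-state level is the mean frame intensity over the last
    quarter of the movie.  Returns the index of the earliest frame above
    ``threshold_frac`` times that level (a movie already bright at frame 0
    returns 0 with a warning); raises if no frame crosses.
    """
    means = movie.frames.reshape(movie.n_frames, -1).mean(axis=1)
    steady = means[-max(movie.n_frames // 4, 1):].mean()
    thresh = threshold_frac * steady
    above = means > thresh
    if not above.any():
        raise ValueError("no light onset found")
    idx = int(np.argmax(above))
    if idx == 0:
        warnings.warn("movie already bright at frame 0", stacklevel=2)
    return idx


def screen_fov(green: Movie, red: Movie, protocol: StimulusProtocol,
               batch: int = 200, n_first_frames: int = 10,
               exclude_stim: bool = True) -> ScreeningMetrics:
    """End-to-end screening analysis of one field of view.

    Chains background/mask estimation, three-term trend fitting with
    stimulation windows excluded, per-pixel divisive detrending,
    SNR-maximizing responsive-pixel selection, per-event response
    amplitudes, and the G/R brightness score.
    """
    bg_g, initial = estimate_background_and_mask(green,
                                                 n_frames=n_first_frames)
    bg_r, _ = estimate_background_and_mask(red, n_frames=1)
    sub = Movie(green.frames.astype(float) - bg_g, green.rate,
                saturation_level=green.saturation_level, channel="green")
    overall = sub.masked_sum_trace(initial)
    exclude = [(ev.onset, ev.onset + ev.duration + 0.3)
               for ev in protocol.events] if exclude_stim else None
    trend = fit_trend(overall, exclude_windows=exclude)
    detr = detrend_divide(sub, trend, mask=initial)
    secondary, snr = select_responsive_mask(detr, initial, protocol,
                                            batch=batch)
    summed = detr.masked_sum_trace(secondary)
    norm = summed.with_values(summed.values / secondary.n_pixels)
    responses = response_amplitude(norm, protocol)
    gr = brightness_ratio(green.frames[:n_first_frames].mean(axis=0) - bg_g,
                          red.frames[0].astype(float) - bg_r, initial)
    return ScreeningMetrics(
        response_amplitudes=[r.amplitude for r in responses],
        brightness_gr=gr, snr=snr, initial_mask=initial,
        secondary_mask=secondary, background_green=bg_g,
        responses=responses)
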
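"""Spectral analyses: PSD, stimulation power maps, coherence, LFP maps.

Welch power spectral density of corrected traces, spectrogram-based power
difference maps at a tagged stimulation frequency (e.g. 40 or 60 Hz air
puff / flicker), magnitude-squared coherence between imaging and LFP
signals, per-ROI LFP correlation maps with a modal best-channel helper,
and shuffled (trial-mismatched) controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._filters import apply_zero_phase, notch
from .datamodel import Movie, Trace


@dataclass
class CoherenceResult:
    frequencies: np.ndarray
    coherence: np.ndarray          # magnitude-squared, in [0, 1]
    segment_s: float
    overlap: float


@dataclass
class PowerMap:
    """Per-ROI power difference (stimulation − baseline) at one frequency."""

    grid: np.ndarray
    target_freq: float
    stim_window: tuple[float, float]
    baseline_window: tuple[float, float]
    roi_size: int


def welch_psd(trace: Trace, nperseg: int | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD (Hann window, 50% overlap, density scaling)."""
    if nperseg is None:
        nperseg = min(trace.n, max(256, trace.n // 8))
    if trace.n < 2 * nperseg // 2:
        raise ValueError("trace too short for Welch estimation")
    return sps.welch(trace.values, fs=trace.rate, nperseg=nperseg)


def psd_peak_frequency(trace: Trace, fmin: float = 0.0,
                       nperseg: int | None = None,
                       refine: str | None = None,
                       centroid_halfwidth: float = 0.75) -> float:
    """Frequency of the largest Welch-PSD value above ``fmin`` Hz.

    With ``refine="centroid"`` the raw argmax bin is replaced by the
    power-weighted centroid of the PSD within ``centroid_halfwidth`` Hz of
    it — the appropriate estimate of the center frequency of a
    frequency-jittered oscillation such as a heartbeat artifact.
    """
    f, p = welch_psd(trace, nperseg=nperseg)
    sel = f > fmin
    if not sel.any():
        raise ValueError("no PSD bins above fmin")
    f, p = f[sel], p[sel]
    fpk = float(f[int(np.argmax(p))])
    if refine == "centroid":
        near = np.abs(f - fpk) <= centroid_halfwidth
        fpk = float(np.sum(f[near] * p[near]) / np.sum(p[near]))
    return fpk


def _spectrogram_power_at(x: np.ndarray, rate: float, target_freq: float,
                          segment_s: float, overlap: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(segment_s * rate))
    noverlap = int(round(overlap * nperseg))
    f, t, sxx = sps.spectrogram(x, fs=rate, window="hann", nperseg=nperseg,
                                noverlap=noverlap)
    row = int(np.argmin(np.abs(f - target_freq)))
    return t, sxx[row]


def power_difference_map(movie: Movie, target_freq: float,
                         stim_window: tuple[float, float],
                         baseline_window: tuple[float, float],
                         roi: int = 2, segment_s: float = 0.5,
                         overlap: float = 0.75) -> PowerMap:
    """Stimulation-minus-baseline spectrogram power at a tagged frequency.

    Each ``roi``×``roi`` block trace gets a Hann spectrogram
    (``segment_s``-long segments, fractional ``overlap``); power in the bin
    nearest ``target_freq`` is averaged over segments centered inside each
    window, and the map holds the stimulation-minus-baseline difference.
    """
    if target_freq >= movie.rate / 2:
        raise ValueError("target frequency at/above Nyquist")
    dur = movie.duration
    for w in (stim_window, baseline_window):
        if w[0] < 0 or w[1] > dur or w[1] - w[0] < segment_s:
            raise ValueError(f"window {w} invalid (outside trial or shorter "
                             "than one spectrogram segment)")
    rows, cols = movie.shape
    nr, nc = rows // roi, cols // roi
    grid = np.empty((nr, nc))
    for i in range(nr):
        for j in range(nc):
            tr = movie.roi_trace(i * roi, j * roi, roi)
            t, p = _spectrogram_power_at(tr.values, movie.rate, target_freq,
                                         segment_s, overlap)
            in_stim = (t >= stim_window[0]) & (t < stim_window[1])
            in_base = (t >= baseline_window[0]) & (t < baseline_window[1])
            if not in_stim.any() or not in_base.any():
                raise ValueError("window shorter than one spectrogram segment")
            grid[i, j] = p[in_stim].mean() - p[in_base].mean()
    return PowerMap(grid=grid, target_freq=target_freq,
                    stim_window=stim_window, baseline_window=baseline_window,
                    roi_size=roi)


def average_power_maps(maps: list[PowerMap]) -> PowerMap:
    """Trial-average of power-difference maps (same geometry required)."""
    first = maps[0]
    if any(m.grid.shape != first.grid.shape
           or m.target_freq != first.target_freq for m in maps):
        raise ValueError("maps must share geometry and target frequency")
    return PowerMap(grid=np.mean([m.grid for m in maps], axis=0),
                    target_freq=first.target_freq,
                    stim_window=first.stim_window,
                    baseline_window=first.baseline_window,
                    roi_size=first.roi_size)


def coherence(a: Trace, b: Trace, segment_s: float = 2.0,
              overlap: float = 0.5) -> CoherenceResult:
    """Welch magnitude-squared coherence between two equal-rate traces."""
    if a.n != b.n or a.rate != b.rate:
        raise ValueError("traces must share length and rate")
    nperseg = int(round(segment_s * a.rate))
    if a.n < 2 * nperseg:
        raise ValueError("record shorter than two coherence segments")
    f, cxy = sps.coherence(a.values, b.values, fs=a.rate, nperseg=nperseg,
                           noverlap=int(round(overlap * nperseg)))
    return CoherenceResult(frequencies=f, coherence=np.clip(cxy, 0.0, 1.0),
                           segment_s=segment_s, overlap=overlap)


def condition_lfp(lfp: Trace, target_rate: float = 200.0,
                  invert: bool = True, lowpass: float = 70.0,
                  notch60: bool = True) -> Trace:
    """Condition an LFP trace to match the imaging clock.

    Order: invert → anti-aliased downsample to ``target_rate`` → zero-phase
    lowpass at ``lowpass`` Hz → optional 60-Hz notch.
    """
    x = -lfp.values if invert else lfp.values.copy()
    factor = lfp.rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("LFP rate must be an integer multiple of target")
    factor = int(round(factor))
    if factor > 1:
        x = sps.resample_poly(x, 1, factor)
    x = apply_zero_phase(x, (None, lowpass), target_rate)
    if notch60:
        x = notch(x, 60.0, target_rate)
    return Trace(x, target_rate, t0_offset=lfp.t0_offset, units=lfp.units)


def correlation_map(movie: Movie, lfp: Trace, roi: int = 2) -> np.ndarray:
    """Pearson correlation of each ROI trace with a conditioned LFP trace.

    The LFP must already be conditioned to the movie's rate (see
    :func:`condition_lfp`).
    """
    if lfp.rate != movie.rate or lfp.n != movie.n_frames:
        raise ValueError("LFP not conditioned to the movie rate/length")
    rows, cols = movie.shape
    nr, nc = rows // roi, cols // roi
    out = np.empty((nr, nc))
    y = lfp.values - lfp.values.mean()
    ny = np.linalg.norm(y)
    for i in range(nr):
        for j in range(nc):
            x = movie.roi_trace(i * roi, j * roi, roi).values
            x = x - x.mean()
            denom = np.linalg.norm(x) * ny
            out[i, j] = float(x @ y / denom) if denom > 0 else 0.0
    return out


def modal_best_channel(roi_traces: list[Trace],
                       lfp_channels: list[Trace]) -> int:
    """Mode over ROIs of the LFP channel with maximum correlation.

    For each ROI trace the channel with the largest Pearson correlation is
    found; the modal channel index across ROIs is returned (smallest index
    wins a tie).
    """
    best = []
    for tr in roi_traces:
        x = tr.values - tr.values.mean()
        rs = []
        for ch in lfp_channels:
            y = ch.values - ch.values.mean()
            denom = np.linalg.norm(x) * np.linalg.norm(y)
            rs.append(float(x @ y / denom) if denom > 0 else 0.0)
        best.append(int(np.argmax(rs)))
    values, counts = np.unique(best, return_counts=True)
    return int(values[int(np.argmax(counts))])


def _derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def shuffled_control(imaging_trials: list[Trace], lfp_trials: list[Trace],
                     n_shuffles: int = 1000, seed: int = 0) -> np.ndarray:
    """Correlation distribution under random trial mismatch.

    Each shuffle pairs imaging trial ``i`` with LFP trial ``σ(i)`` for a
    seeded random derangement σ (no trial keeps its own partner) and
    records the Pearson correlation of every mismatched pair.  Returns an
    ``(n_shuffles, n_trials)`` array.
    """
    n = len(imaging_trials)
    if n < 2 or len(lfp_trials) != n:
        raise ValueError("need at least 2 matched trials")
    rng = np.random.default_rng(seed)
    img = np.stack([tr.values - tr.values.mean() for tr in imaging_trials])
    lfp = np.stack([tr.values - tr.values.mean() for tr in lfp_trials])
    img_n = np.linalg.norm(img, axis=1)
    lfp_n = np.linalg.norm(lfp, axis=1)
    out = np.empty((n_shuffles, n))
    for s in range(n_shuffles):
        perm = _derangement(rng, n)
        num = np.einsum("ij,ij->i", img, lfp[perm])
        denom = img_n * lfp_n[perm]
        out[s] = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    return out


def matched_correlations(imaging_trials: list[Trace],
                         lfp_trials: list[Trace]) -> np.ndarray:
    """Pearson correlation of each matched imaging/LFP trial pair."""
    out = []
    for a, b in zip(imaging_trials, lfp_trials):
        x = a.values - a.values.mean()
        y = b.values - b.values.mean()
        denom = np.linalg.norm(x) * np.linalg.norm(y)
        out.append(float(x @ y / denom) if denom > 0 else 0.0)
    return np.asarray(out)
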
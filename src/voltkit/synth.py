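"""Seeded generators for synthetic voltage-imaging inputs.

Every analysis stage in the toolkit can be exercised without downloads: the
generators here produce dual-channel widefield movies with a hidden voltage
signal, heartbeat and slow hemodynamic artifacts shared across channels,
bi-exponential photobleaching and shared illumination noise; step-response
fluorescence traces following the onset-exponential kinetics model;
spike-train fluorescence traces; and screening fields of view with
responsive cells under electric field stimulation (EFS).

Identical ``(config, seed)`` pairs produce bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._filters import apply_zero_phase
from .datamodel import (DualChannelRecording, Movie, PixelMask,
                        StimulusEvent, StimulusProtocol, Trace)
from .kinetics import exp_onset_model


def bleach_curve(t: np.ndarray, params: Sequence[float]) -> np.ndarray:
    """Two-term exponential bleach ``A1·e^{λ1 t} + A2·e^{λ2 t}`` (λ < 0)."""
    a1, l1, a2, l2 = params
    if l1 >= 0 or l2 >= 0:
        raise ValueError("bleach rates must be negative")
    return a1 * np.exp(l1 * t) + a2 * np.exp(l2 * t)


@dataclass
class MovieSimConfig:
    """Parameters of the dual-channel widefield movie generator.

    Defaults emulate an anesthetized-mouse trial: 200-Hz dual-camera
    acquisition, 20.48-s trials, a ~5-Hz heartbeat artifact present in both
    channels, slow hemodynamics below 1 Hz, bi-exponential photobleaching of
    the indicator channel, and illumination noise shared between channels
    (single light source).  Artifact and noise amplitudes are fractions of
    the mean fluorescence.  The spatial grid is a scaled-down 32×32 field:
    all per-ROI analyses are spatially local, so grid size does not change
    the statistics being tested.
    """

    shape: tuple[int, int] = (32, 32)
    rate: float = 200.0
    duration: float = 20.48
    heartbeat_hz: float = 5.0          # ~5 Hz anesthetized, 10-14 Hz awake
    heartbeat_amp: float = 0.02
    heartbeat_jitter: float = 0.05     # fractional random-walk frequency jitter
    slow_hemo_band: tuple[float, float] = (0.1, 1.0)
    slow_hemo_amp: float = 0.01
    bleach_params: tuple[float, float, float, float] = (0.04, -0.5, 0.96, -5e-4)
    voltage_signal: Trace | None = None  # None -> band-limited default
    voltage_amp: float = 0.01
    voltage_band: tuple[float, float] = (0.3, 15.0)
    voltage_exponent: float = 2.0      # PSD slope: power ∝ f^-exponent
    shared_noise_sd: float = 0.005
    shared_noise_band: tuple[float | None, float] = (None, 10.0)
    independent_noise_sd: float = 0.003
    background_level: float = 100.0
    green_level: float = 2000.0
    red_level: float = 1500.0
    red_heartbeat_gain: float = 1.3    # artifact gain of red relative to green
    red_hemo_gain: float = 1.3
    noise_model: str = "gaussian"      # or "poisson"

    def __post_init__(self) -> None:
        for name in ("heartbeat_amp", "slow_hemo_amp", "shared_noise_sd",
                     "independent_noise_sd", "voltage_amp"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.heartbeat_hz >= self.rate / 2:
            raise ValueError("heartbeat frequency at/above Nyquist")
        if self.bleach_params[1] >= 0 or self.bleach_params[3] >= 0:
            raise ValueError("bleach rates must be negative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be gaussian or poisson")

    @classmethod
    def anesthetized(cls, **kw) -> "MovieSimConfig":
        return cls(heartbeat_hz=kw.pop("heartbeat_hz", 5.0), **kw)

    @classmethod
    def awake(cls, **kw) -> "MovieSimConfig":
        return cls(heartbeat_hz=kw.pop("heartbeat_hz", 12.0), **kw)


@dataclass
class MovieGroundTruth:
    """Hidden components of a generated dual-channel movie.

    The clean voltage ΔF/F component of pixel (i, j) is
    ``voltage.values * voltage_gain[i, j]``.
    """

    voltage: Trace
    voltage_gain: np.ndarray
    heartbeat: np.ndarray
    slow_hemo: np.ndarray
    bleach: np.ndarray
    shared_noise: np.ndarray
    clipped: bool = False

    def clean_dff(self, row: int, col: int, size: int = 1) -> np.ndarray:
        """Clean voltage ΔF/F of the ``size``×``size`` ROI at (row, col)."""
        gain = float(self.voltage_gain[row:row + size, col:col + size].mean())
        return self.voltage.values * gain


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  lo: float = 0.8, hi: float = 1.2) -> np.ndarray:
    """Smooth spatial gain map in [lo, hi] (coarse noise, bilinear upsample)."""
    coarse = rng.standard_normal((4, 4))
    r = np.linspace(0, 3, shape[0])
    c = np.linspace(0, 3, shape[1])
    r0 = np.floor(r).astype(int).clip(0, 2)
    c0 = np.floor(c).astype(int).clip(0, 2)
    fr, fc = r - r0, c - c0
    f = (coarse[np.ix_(r0, c0)] * np.outer(1 - fr, 1 - fc)
         + coarse[np.ix_(r0 + 1, c0)] * np.outer(fr, 1 - fc)
         + coarse[np.ix_(r0, c0 + 1)] * np.outer(1 - fr, fc)
         + coarse[np.ix_(r0 + 1, c0 + 1)] * np.outer(fr, fc))
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    return lo + (hi - lo) * f


def _heartbeat_wave(rng: np.random.Generator, n: int, rate: float,
                    f0: float, jitter: float) -> np.ndarray:
    """Unit-amplitude heartbeat: sinusoid with random-walk frequency jitter
    (bounded at ±``jitter`` fractionally) and slow amplitude modulation."""
    walk = np.cumsum(rng.standard_normal(n)) / np.sqrt(max(n, 1))
    walk = apply_zero_phase(walk, (None, 0.2), rate)
    walk = np.clip(walk / max(np.abs(walk).max(), 1e-12), -1, 1)
    inst_freq = f0 * (1 + jitter * walk)
    phase = 2 * np.pi * np.cumsum(inst_freq) / rate
    am = apply_zero_phase(rng.standard_normal(n), (None, 0.3), rate)
    am = 1 + 0.2 * np.clip(am / max(np.std(am), 1e-12), -2, 2) / 2
    return am * np.sin(phase)


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                band: tuple[float, float], sd: float) -> np.ndarray:
    """Gaussian noise band-limited to ``band`` and rescaled to ``sd``."""
    x = apply_zero_phase(rng.standard_normal(n), band, rate)
    s = np.std(x)
    return x * (sd / s) if s > 0 else x


def default_voltage_signal(rate: float, duration: float, amp: float,
                           band: tuple[float, float],
                           rng: np.random.Generator,
                           exponent: float = 2.0) -> Trace:
    """Band-limited 1/f^exponent Gaussian process emulating cortical ΔF/F.

    Cortical voltage and field-potential spectra fall steeply with
    frequency (power roughly ∝ 1/f² below ~10 Hz); a spectrally flat
    default would grossly over-weight high frequencies.  The signal is
    shaped in the Fourier domain within ``band`` and rescaled to standard
    deviation ``amp``.
    """
    n = int(round(duration * rate))
    if amp == 0:
        return Trace(np.zeros(n), rate, units="dF/F")
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spec = (rng.standard_normal(freqs.size)
            + 1j * rng.standard_normal(freqs.size))
    shape = np.zeros(freqs.size)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    shape[in_band] = freqs[in_band] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = np.std(x)
    return Trace(x * (amp / sd) if sd > 0 else x, rate, units="dF/F")


def gen_dual_channel_movie(cfg: MovieSimConfig, seed: int
                           ) -> tuple[DualChannelRecording, MovieGroundTruth]:
    """Generate a paired green/red widefield movie with known ground truth.

    Composition (fractions of mean channel fluorescence)::

        green = bg + G0·B(t)·(1 + v·gv + h·gh + s·gs + shared + eps_g)
        red   = bg + R0·(1 + h·gh' + s·gs' + shared + eps_r)

    where ``v`` is the voltage signal (green only), ``h`` the heartbeat,
    ``s`` slow hemodynamics, ``shared`` illumination noise identical in both
    channels, and ``eps`` independent sensor noise.  ``B(t)`` is the
    two-term exponential bleach, applied multiplicatively to the green
    channel only (no apparent bleaching of the red reference).
    """
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration * cfg.rate))
    t = np.arange(n) / cfg.rate
    rows, cols = cfg.shape

    hb = cfg.heartbeat_amp * _heartbeat_wave(rng, n, cfg.rate,
                                             cfg.heartbeat_hz,
                                             cfg.heartbeat_jitter)
    if cfg.slow_hemo_amp > 0:
        hemo = _band_noise(rng, n, cfg.rate, cfg.slow_hemo_band,
                           cfg.slow_hemo_amp)
    else:
        hemo = np.zeros(n)
    if cfg.voltage_signal is not None:
        v = np.asarray(cfg.voltage_signal.values, dtype=float)
        if v.size != n:
            raise ValueError("voltage_signal length does not match duration")
        voltage = Trace(v, cfg.rate, units="dF/F")
    else:
        voltage = default_voltage_signal(cfg.rate, cfg.duration,
                                         cfg.voltage_amp, cfg.voltage_band,
                                         rng, exponent=cfg.voltage_exponent)
    if cfg.shared_noise_sd > 0:
        # illumination fluctuations are slow (LED/laser drift and ripple),
        # which is what lets the reference channel correct them
        shared = apply_zero_phase(rng.standard_normal(n),
                                  cfg.shared_noise_band, cfg.rate)
        shared *= cfg.shared_noise_sd / max(np.std(shared), 1e-12)
    else:
        shared = np.zeros(n)
    bleach = bleach_curve(t, cfg.bleach_params)

    gv = _smooth_field(rng, cfg.shape)           # voltage gain (green only)
    gh_g = _smooth_field(rng, cfg.shape)         # heartbeat gain maps
    gh_r = cfg.red_heartbeat_gain * gh_g         # shared spatial pattern
    gs_g = _smooth_field(rng, cfg.shape)
    gs_r = cfg.red_hemo_gain * gs_g

    # time-major composition; broadcasting (n,1,1)*(rows,cols)
    def _tx(x: np.ndarray) -> np.ndarray:
        return x[:, None, None]

    green_frac = (1.0
                  + _tx(voltage.values) * gv
                  + _tx(hb) * gh_g
                  + _tx(hemo) * gs_g
                  + _tx(shared))
    red_frac = (1.0
                + _tx(hb) * gh_r
                + _tx(hemo) * gs_r
                + _tx(shared))
    if cfg.independent_noise_sd > 0:
        green_frac = green_frac + cfg.independent_noise_sd * \
            rng.standard_normal((n, rows, cols))
        red_frac = red_frac + cfg.independent_noise_sd * \
            rng.standard_normal((n, rows, cols))

    green = cfg.background_level + cfg.green_level * _tx(bleach) * green_frac
    red = cfg.background_level + cfg.red_level * red_frac
    if cfg.noise_model == "poisson":
        green = rng.poisson(np.clip(green, 0, None)).astype(float)
        red = rng.poisson(np.clip(red, 0, None)).astype(float)

    clipped = bool((green < 0).any() or (red < 0).any())
    if clipped:
        warnings.warn("negative intensities clipped to zero", stacklevel=2)
        green = np.clip(green, 0, None)
        red = np.clip(red, 0, None)

    rec = DualChannelRecording(
        green=Movie(green, cfg.rate, channel="green"),
        red=Movie(red, cfg.rate, channel="red"),
        trial_id=f"synth-{seed}",
        metadata={"seed": seed, "heartbeat_hz": cfg.heartbeat_hz})
    gt = MovieGroundTruth(voltage=voltage, voltage_gain=gv, heartbeat=hb,
                          slow_hemo=hemo, bleach=bleach, shared_noise=shared,
                          clipped=clipped)
    return rec, gt


def gen_step_trace(model_params: dict, rate: float, duration: float,
                   noise_sd: float, seed: int, t_start: float = 0.0) -> Trace:
    """Step-response fluorescence trace from the onset-exponential model.

    ``model_params`` holds ``c`` (plateau), ``k`` (amplitude), ``lam``
    (rate, s⁻¹, negative), ``t0`` (onset, s) and optionally ``k2``/``lam2``
    for the dual model.  The noiseless part evaluates the model exactly;
    Gaussian noise of standard deviation ``noise_sd`` is added on top.
    """
    lam = model_params["lam"]
    lam2 = model_params.get("lam2")
    if lam >= 0 or (lam2 is not None and lam2 >= 0):
        raise ValueError("exponential rates must be negative")
    t0 = model_params["t0"]
    if not (t_start <= t0 <= t_start + duration):
        raise ValueError("onset t0 outside the trace span")
    n = int(round(duration * rate))
    t = t_start + np.arange(n) / rate
    f = exp_onset_model(t, model_params["c"], model_params["k"], lam, t0,
                        k2=model_params.get("k2", 0.0), lam2=lam2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + noise_sd * rng.standard_normal(n)
    return Trace(f, rate, t0_offset=t_start, units="F", polarity="negative_up")


def gen_spike_trace(spike_times: Sequence[float], amplitude: float,
                    width_fwhm: float, noise_sd: float, rate: float,
                    duration: float, seed: int,
                    drift_spec: tuple[float, float] | None = None
                    ) -> tuple[Trace, np.ndarray]:
    """Fluorescence trace with negative-going Gaussian spikes at known times.

    ``amplitude`` is the (positive) spike depth; ``drift_spec`` optionally
    adds a slow sinusoid ``(amp, freq_hz)``.  Returns the trace (polarity
    ``negative_up``) and the ground-truth spike times.
    """
    times = np.sort(np.asarray(spike_times, dtype=float))
    if times.size and (times[0] < 0 or times[-1] >= duration):
        raise ValueError("spike times must lie within the record")
    if width_fwhm < 2.0 / rate:
        raise ValueError("spike width below two samples")
    if times.size > 1 and np.min(np.diff(times)) < width_fwhm:
        warnings.warn("spikes closer than their width overlap", stacklevel=2)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    sigma = width_fwhm / (2 * np.sqrt(2 * np.log(2)))
    f = np.zeros(n)
    for ts in times:
        m = np.abs(t - ts) < 5 * sigma
        f[m] -= amplitude * np.exp(-0.5 * ((t[m] - ts) / sigma) ** 2)
    if drift_spec is not None:
        damp, dfreq = drift_spec
        f = f + damp * np.sin(2 * np.pi * dfreq * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + noise_sd * rng.standard_normal(n)
    return Trace(f, rate, units="dF/F", polarity="negative_up"), times


def screening_efs_protocol(light_onset: float = 0.0) -> StimulusProtocol:
    """The plate-screening EFS protocol, referenced to light onset.

    Four 1-ms monophasic pulses with a 500-ms period starting 1 s after
    light onset, then a 1-s gap, then a 100-Hz train of ten 2.5-ms pulses
    (10-ms period) treated as a single train event.
    """
    events = [StimulusEvent(onset=light_onset + 1.0 + 0.5 * i, duration=1e-3,
                            kind="efs_pulse", amplitude=60.0)
              for i in range(4)]
    events.append(StimulusEvent(onset=light_onset + 3.5, duration=0.1,
                                kind="efs_train", frequency=100.0,
                                amplitude=30.0))
    return StimulusProtocol(events)


@dataclass
class ScreenGroundTruth:
    """Hidden structure of a synthetic screening field of view."""

    cell_mask: PixelMask
    responsive_mask: PixelMask
    event_amplitudes: np.ndarray     # per-event peak ΔF/F (signed)
    cell_centers: list[tuple[int, int]] = field(default_factory=list)


def gen_screen_fov(n_cells: int, response_amp: float,
                   efs_protocol: StimulusProtocol,
                   bleach_params: Sequence[float],
                   frac_nonresponsive: float, seed: int,
                   shape: tuple[int, int] = (64, 64), rate: float = 200.0,
                   duration: float = 5.0, cell_radius: int = 4,
                   noise_sd: float = 0.0, background_level: float = 100.0,
                   cell_level: float = 1200.0, decay_tau: float = 0.05
                   ) -> tuple[Movie, Movie, StimulusProtocol, ScreenGroundTruth]:
    """Synthetic screening FOV: disk-shaped cells over a dark background.

    A fraction ``1 - frac_nonresponsive`` of cell pixels carry EFS-locked
    negative-going transients of fractional amplitude ``response_amp``
    (signed; this indicator family is negative-going, so pass a negative
    value) decaying with time constant ``decay_tau``.  Returns the green
    movie, a single-frame red reference movie proportional to the cell
    footprint, the protocol, and the ground truth.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if not -1 < response_amp < 1:
        raise ValueError("response_amp must be a fraction in (-1, 1)")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    if 2 * cell_radius + 2 >= min(rows, cols):
        raise ValueError("cells exceed frame bounds")
    efs_protocol.check_within(duration)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    cell_mask = np.zeros(shape, dtype=bool)
    centers: list[tuple[int, int]] = []
    rr, cc = np.mgrid[0:rows, 0:cols]
    for _ in range(n_cells):
        r0 = int(rng.integers(cell_radius + 1, rows - cell_radius - 1))
        c0 = int(rng.integers(cell_radius + 1, cols - cell_radius - 1))
        centers.append((r0, c0))
        cell_mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= cell_radius ** 2

    cell_idx = np.flatnonzero(cell_mask.ravel())
    n_resp = int(round((1 - frac_nonresponsive) * cell_idx.size))
    resp_idx = rng.choice(cell_idx, size=n_resp, replace=False)
    resp_mask = np.zeros(rows * cols, dtype=bool)
    resp_mask[resp_idx] = True
    resp_mask = resp_mask.reshape(shape)

    # EFS-locked transient: instantaneous onset, exponential decay
    s = np.zeros(n)
    for ev in efs_protocol.events:
        m = t >= ev.onset
        s[m] += np.exp(-(t[m] - ev.onset) / decay_tau)
    s = np.clip(s, None, 1.0) * response_amp
    event_amps = np.full(len(efs_protocol), response_amp)

    bleach = bleach_curve(t, bleach_params)
    frac = 1.0 + s[:, None, None] * resp_mask[None, :, :]
    green = background_level + cell_level * cell_mask[None, :, :] \
        * bleach[:, None, None] * frac
    if noise_sd > 0:
        green = green + cell_level * noise_sd * \
            rng.standard_normal((n, rows, cols))
    red_frame = background_level + 0.6 * cell_level * cell_mask.astype(float)

    gt = ScreenGroundTruth(cell_mask=PixelMask(cell_mask),
                           responsive_mask=PixelMask(resp_mask),
                           event_amplitudes=event_amps,
                           cell_centers=centers)
    return (Movie(green, rate, channel="green"),
            Movie(red_frame[None, :, :], rate, channel="red"),
            efs_protocol, gt)
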
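"""Zero-phase Butterworth filtering helpers shared across modules.

All filters are 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), i.e. zero phase with band edges at half power.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def _check_edge(edge: float, rate: float) -> None:
    if edge >= rate / 2:
        raise ValueError(f"filter edge {edge} Hz at/above Nyquist ({rate / 2} Hz)")
    if edge <= 0:
        raise ValueError(f"filter edge must be positive, got {edge}")


def butter_sos(band: tuple[float | None, float | None], rate: float,
               order: int = 4) -> np.ndarray:
    """SOS coefficients for a (low, high) band at sampling ``rate``.

    ``low=None`` gives a lowpass at ``high``; ``high=None`` a highpass at
    ``low``; both set gives a bandpass.
    """
    low, high = band
    if low is None and high is None:
        raise ValueError("band must set at least one edge")
    if low is None:
        _check_edge(high, rate)
        return signal.butter(order, high, btype="lowpass", fs=rate, output="sos")
    if high is None:
        _check_edge(low, rate)
        return signal.butter(order, low, btype="highpass", fs=rate, output="sos")
    _check_edge(high, rate)
    if low >= high:
        raise ValueError(f"band low {low} >= high {high}")
    return signal.butter(order, [low, high], btype="bandpass", fs=rate,
                         output="sos")


def apply_zero_phase(values: np.ndarray, band: tuple[float | None, float | None],
                     rate: float, order: int = 4, axis: int = -1) -> np.ndarray:
    """Forward-backward filter ``values`` along ``axis``."""
    sos = butter_sos(band, rate, order=order)
    return signal.sosfiltfilt(sos, values, axis=axis)


def notch(values: np.ndarray, freq: float, rate: float, q: float = 30.0,
          axis: int = -1) -> np.ndarray:
    """Zero-phase IIR notch at ``freq`` Hz (quality factor ``q``)."""
    b, a = signal.iirnotch(freq, q, fs=rate)
    return signal.filtfilt(b, a, values, axis=axis)


def sharp_band_filter(values: np.ndarray,
                      band: tuple[float | None, float | None], rate: float,
                      transition: float = 0.3) -> np.ndarray:
    """Zero-phase frequency-domain filter with raised-cosine transitions.

    Passband gain is exactly 1 away from the edges, with a raised-cosine
    roll-off of total width ``transition`` Hz centered on each edge; the
    stopband is fully suppressed.  Intended for the regression band
    filters, where a regressor attenuated inside its nominal band (as a
    low-order IIR response would be near the edges) leaves artifact
    amplitude that no scale coefficient can remove.  A line through the
    record's endpoints is removed before the transform to suppress
    wrap-around leakage (and restored for pure lowpass bands, where it is
    passband content).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    low, high = band
    if high is not None:
        _check_edge(high, rate)
    if low is not None and low <= 0:
        raise ValueError("low edge must be positive (None for lowpass)")

    t = np.arange(n)
    line = x[0] + (x[-1] - x[0]) * t / max(n - 1, 1)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)

    def edge_response(f: np.ndarray, fc: float, rising: bool) -> np.ndarray:
        h = np.clip((f - (fc - transition / 2)) / transition, 0.0, 1.0)
        h = 0.5 - 0.5 * np.cos(np.pi * h)      # raised cosine 0 -> 1
        return h if rising else 1.0 - h

    h = np.ones_like(freqs)
    if low is not None:
        h *= edge_response(freqs, low, rising=True)
    if high is not None:
        h *= edge_response(freqs, high, rising=False)
    y = np.fft.irfft(np.fft.rfft(x - line) * h, n=n)
    if low is None:
        y = y + line
    return y
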
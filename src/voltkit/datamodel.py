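"""Core in-memory containers for voltage-imaging data.

All time indexing is zero-based and time-major: the time of sample/frame
``i`` of an object with sampling ``rate`` is ``t0_offset + i / rate``
seconds.  Movies are stored ``(frame, row, col)`` so that per-pixel trace
extraction is contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Literal, Sequence

import numpy as np

Polarity = Literal["positive_up", "negative_up"]

EVENT_KINDS = ("efs_pulse", "efs_train", "step", "ap_waveform", "air_puff",
               "flicker", "whisker")


@dataclass
class Trace:
    """Uniformly sampled scalar time series (fluorescence, voltage, or LFP).

    Parameters
    ----------
    values : array-like
        Sample values in ``units``.
    rate : float
        Sampling rate in Hz; must be positive.
    t0_offset : float, optional
        Time of sample 0 in seconds (default 0).
    units : str, optional
        Unit label, e.g. ``"counts"``, ``"dF/F"``, ``"mV"``.
    polarity : {"positive_up", "negative_up"}
        Direction of physiological deflections.  GFP-based voltage
        indicators of this family are negative-going on depolarization.
    """

    values: np.ndarray
    rate: float
    t0_offset: float = 0.0
    units: str = "a.u."
    polarity: Polarity = "positive_up"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be one-dimensional")
        if not self.rate > 0:
            raise ValueError("Trace rate must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / rate)."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, ``t0_offset + i / rate``."""
        return self.t0_offset + np.arange(self.n) / self.rate

    def index_at(self, t: float) -> int:
        """Index of the sample at time ``t`` (nearest, clipped to range)."""
        i = int(round((t - self.t0_offset) * self.rate))
        return min(max(i, 0), self.n - 1)

    def slice_time(self, start: float, stop: float) -> "Trace":
        """Sub-trace covering the half-open window ``[start, stop)`` seconds."""
        i0 = max(int(np.ceil((start - self.t0_offset) * self.rate - 1e-9)), 0)
        i1 = min(int(np.ceil((stop - self.t0_offset) * self.rate - 1e-9)), self.n)
        if i1 <= i0:
            raise ValueError(f"empty time slice [{start}, {stop})")
        return Trace(self.values[i0:i1], self.rate,
                     t0_offset=self.t0_offset + i0 / self.rate,
                     units=self.units, polarity=self.polarity)

    def with_values(self, values: np.ndarray) -> "Trace":
        """Copy of this trace with the same clock but new samples."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class Movie:
    """Time-major fluorescence movie, ``frames[t, row, col]`` in counts."""

    frames: np.ndarray
    rate: float
    saturation_level: float = 65535.0
    channel: Literal["green", "red"] = "green"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("Movie frames must be 3-D (time, rows, cols)")
        if self.frames.shape[0] < 1:
            raise ValueError("Movie needs at least one frame")
        if not self.rate > 0:
            raise ValueError("Movie rate must be positive")
        if not self.saturation_level > 0:
            raise ValueError("saturation_level must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, cols)."""
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate

    def pixel_trace(self, row: int, col: int) -> Trace:
        return Trace(self.frames[:, row, col].astype(float), self.rate,
                     units="counts")

    def roi_trace(self, row: int, col: int, size: int = 2) -> Trace:
        """Mean trace of the ``size``×``size`` block with top-left (row, col)."""
        block = self.frames[:, row:row + size, col:col + size]
        return Trace(block.reshape(block.shape[0], -1).mean(axis=1),
                     self.rate, units="counts")

    def masked_sum_trace(self, mask: "PixelMask") -> Trace:
        """Frame-by-frame sum over the pixels selected by ``mask``."""
        if mask.grid.shape != self.shape:
            raise ValueError("mask shape does not match movie")
        flat = self.frames.reshape(self.n_frames, -1)
        return Trace(flat[:, mask.grid.ravel()].sum(axis=1), self.rate,
                     units="counts")


@dataclass
class DualChannelRecording:
    """Paired green (indicator) and red (reference) movies on a common clock."""

    green: Movie
    red: Movie
    trial_id: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.green.frames.shape != self.red.frames.shape:
            raise ValueError("green and red movies must share shape")
        if self.green.rate != self.red.rate:
            raise ValueError("green and red movies must share rate")

    @property
    def rate(self) -> float:
        return self.green.rate

    @property
    def n_frames(self) -> int:
        return self.green.n_frames


@dataclass
class StimulusEvent:
    onset: float
    duration: float
    kind: str = "efs_pulse"
    frequency: float | None = None
    amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class StimulusProtocol:
    """Ordered list of stimulation events (onsets non-decreasing)."""

    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events], dtype=float)

    def shifted(self, dt: float) -> "StimulusProtocol":
        """Protocol with every onset moved by ``dt`` seconds (re-referencing)."""
        return StimulusProtocol([replace(e, onset=e.onset + dt)
                                 for e in self.events])

    def check_within(self, duration: float) -> None:
        for e in self.events:
            if e.onset < 0 or e.onset + e.duration > duration:
                raise ValueError(
                    f"event at {e.onset}s exceeds recording span {duration}s")


@dataclass
class PixelMask:
    """Boolean grid selecting pixels of a field of view."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("PixelMask grid must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.grid.sum())

    def is_subset_of(self, other: "PixelMask") -> bool:
        return bool(np.all(~self.grid | other.grid))

    def indices(self) -> np.ndarray:
        """Flat indices of selected pixels (row-major)."""
        return np.flatnonzero(self.grid.ravel())


# Band-regression presets: high-to-low frequency, matching the published
# step order.  ``None`` as a low edge means a pure lowpass band.
AWAKE_BANDS: tuple[tuple[float | None, float], ...] = (
    (10.0, 30.0), (1.0, 10.0), (None, 1.0))
ANESTHETIZED_BANDS: tuple[tuple[float | None, float], ...] = (
    (4.0, 20.0), (1.0, 4.0), (None, 1.0))
AWAKE_LFP_BANDS: tuple[tuple[float | None, float], ...] = (
    (14.0, 30.0), (10.0, 14.0), (5.0, 10.0), (1.0, 5.0), (None, 1.0))


@dataclass
class RunConfig:
    """Preprocessing configuration for the dual-channel pipeline.

    ``band_edges`` are ordered high→low; ``mode`` selects the published
    defaults (awake: 10–30, 1–10, 0–1 Hz; anesthetized: 4–20, 1–4,
    0–1 Hz) unless custom edges are supplied.
    """

    band_edges: Sequence[tuple[float | None, float]] | None = None
    baseline_window: tuple[float, float] = (2.0, 2.5)
    lowpass_cutoff: float = 70.0
    mode: Literal["awake", "anesthetized", "custom"] = "awake"
    seed: int = 0
    roi_size: int = 2

    def __post_init__(self) -> None:
        if self.band_edges is None:
            if self.mode == "awake":
                self.band_edges = AWAKE_BANDS
            elif self.mode == "anesthetized":
                self.band_edges = ANESTHETIZED_BANDS
            else:
                raise ValueError("custom mode requires explicit band_edges")
        self.band_edges = tuple((lo, hi) for lo, hi in self.band_edges)
        for lo, hi in self.band_edges:
            if lo is not None and lo >= hi:
                raise ValueError(f"band ({lo}, {hi}) has low >= high")
        # bands must be ordered high->low and non-overlapping
        highs = [hi for _, hi in self.band_edges]
        if any(b > a for a, b in zip(highs, highs[1:])):
            raise ValueError("bands must be ordered high to low frequency")
        if self.baseline_window[1] <= self.baseline_window[0]:
            raise ValueError("empty baseline window")
        if self.roi_size < 1:
            raise ValueError("roi_size must be >= 1")

    def validate_for(self, rate: float, duration: float) -> None:
        if self.lowpass_cutoff >= rate / 2:
            raise ValueError("lowpass cutoff must be below Nyquist")
        if self.baseline_window[1] > duration:
            raise ValueError("baseline window outside the trial")
        for lo, hi in self.band_edges:
            if hi >= rate / 2:
                raise ValueError(f"band edge {hi} Hz at/above Nyquist")
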
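"""Spike detection and precision/recall/F1 scoring with time-bin matching.

Ground-truth spikes come from the command-voltage waveform; detected spikes
come from the (negative-going) fluorescence trace after 60-Hz high-pass
filtering and a 2σ amplitude threshold.  Matching walks the ground truth
first-to-last: each truth spike pairs with the nearest unmatched detection
within ± the time bin (ties to the earlier detection) and both are removed.
The time bin defaults to the minimum inter-spike interval of the truth
train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._filters import apply_zero_phase
from .datamodel import Trace


@dataclass
class SpikeMatchResult:
    """Confusion counts and scores of a spike-train comparison."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    time_bin: float
    matched_pairs: list[tuple[float, float]] = field(default_factory=list)

    def summary(self) -> str:
        return (f"TP={self.tp} FP={self.fp} FN={self.fn}  "
                f"P={self.precision:.3f} R={self.recall:.3f} "
                f"F1={self.f1:.3f}  bin={self.time_bin * 1e3:.3g} ms")


def detect_command_spikes(voltage: Trace, prominence: float = 10.0,
                          min_distance: float = 0.001) -> np.ndarray:
    """Spike times in a command-voltage trace (mV).

    Local maxima with prominence ≥ 10 mV separated by ≥ 1 ms, following
    the standard peak-finding convention (the higher of two peaks closer
    than the minimum distance is kept).
    """
    if voltage.n == 0:
        raise ValueError("empty trace")
    dist = max(int(round(min_distance * voltage.rate)), 1)
    peaks, _ = find_peaks(voltage.values, prominence=prominence,
                          distance=dist)
    return voltage.t0_offset + peaks / voltage.rate


def detect_fluor_spikes(trace: Trace, baseline_window: float = 0.5,
                        threshold_mult: float = 2.0,
                        highpass: float = 60.0) -> np.ndarray:
    """Threshold spike detection in a fluorescence trace.

    The trace is rectified according to its polarity (negative-going
    indicators are inverted so spikes point up), high-pass filtered at
    ``highpass`` Hz to remove slow components, and peaks larger than
    ``threshold_mult`` times the noise level σ are returned.  σ is the
    standard deviation of the filtered trace over the first
    ``baseline_window`` seconds, which must be spike-free by contract.
    """
    if baseline_window > trace.duration:
        raise ValueError("baseline window exceeds the record")
    x = trace.values.astype(float)
    if trace.polarity == "negative_up":
        x = -x
    x = apply_zero_phase(x, (highpass, None), trace.rate)
    n_base = int(round(baseline_window * trace.rate))
    sigma = float(np.std(x[:n_base]))
    if sigma == 0:
        sigma = np.finfo(float).tiny
    peaks, _ = find_peaks(x, height=threshold_mult * sigma)
    return trace.t0_offset + peaks / trace.rate


def auto_time_bin(truth_times: np.ndarray) -> float:
    """Matching bin = minimum distance between neighboring truth spikes."""
    truth_times = np.sort(np.asarray(truth_times, dtype=float))
    if truth_times.size < 2:
        raise ValueError("auto time bin needs at least 2 truth spikes")
    return float(np.min(np.diff(truth_times)))


def window_spikes(times: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Restrict spike times to the half-open window ``[start, stop)``."""
    times = np.asarray(times, dtype=float)
    return times[(times >= start) & (times < stop)]


def match_and_score(truth_times, detected_times,
                    time_bin: float | None = None) -> SpikeMatchResult:
    """Greedy first-to-last matching of detections to ground-truth spikes.

    Each truth spike (in time order) is matched to the nearest unmatched
    detection within ± ``time_bin`` (tie broken toward the earlier
    detection) and the pair is removed.  Precision, recall, and
    F1 = 2PR/(P+R) follow; empty-input conventions: no detections and no
    truth ⇒ perfect silence (P=R=F1=1); otherwise an empty side scores 0.
    """
    truth = np.sort(np.asarray(truth_times, dtype=float))
    det = np.sort(np.asarray(detected_times, dtype=float))
    if time_bin is None:
        time_bin = auto_time_bin(truth)
    if time_bin <= 0:
        raise ValueError("time_bin must be positive")

    unmatched = list(det)
    pairs: list[tuple[float, float]] = []
    for ts in truth:
        if not unmatched:
            break
        d = np.abs(np.asarray(unmatched) - ts)
        j = int(np.argmin(d))        # argmin returns the first (earlier) tie
        if d[j] <= time_bin:
            pairs.append((float(ts), float(unmatched.pop(j))))

    tp = len(pairs)
    fp = det.size - tp
    fn = truth.size - tp
    if truth.size == 0 and det.size == 0:
        precision = recall = f1 = 1.0
    else:
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if (precision + recall) > 0 else 0.0)
    return SpikeMatchResult(tp=tp, fp=fp, fn=fn, precision=precision,
                            recall=recall, f1=f1, time_bin=float(time_bin),
                            matched_pairs=pairs)
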
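"""Exponential-with-onset kinetics fitting for step-response traces.

The response of a voltage indicator to a command-voltage step is modeled as
a constant before a fitted onset time ``t0`` and a mono- or bi-exponential
relaxation toward a plateau after it::

    F(t) = c + k·exp((t − t0)·λ)                       (t > t0)
    F(t) = c + k                                       (t ≤ t0)

and, for the dual model,

    F(t) = c + k·exp((t − t0)·λ) + k2·exp((t − t0)·λ2)  (t > t0)
    F(t) = c + k + k2                                    (t ≤ t0)

where ``c`` is the plateau fluorescence, ``k``/``k2`` the component
amplitudes, ``λ``/``λ2`` (negative, s⁻¹) the opposite reciprocals of the
time constants, and ``t0`` the event onset.  The model is continuous at
``t0``.  Time constants are reported in milliseconds as ``τ = −1000/λ``;
for dual fits the *fraction fast* is ``100·|k_fast|/(|k_fast|+|k_slow|)``.

Fitting uses variable projection: for fixed ``(t0, λ, λ2)`` the model is
linear in ``(c, k, k2)``, which are solved by linear least squares inside a
nonlinear search over onset and log-rates, multi-started over an onset grid
and log-spaced rate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .datamodel import Trace


def exp_onset_model(t: np.ndarray, c: float, k: float, lam: float, t0: float,
                    k2: float = 0.0, lam2: float | None = None) -> np.ndarray:
    """Evaluate the onset-exponential model (mono if ``lam2`` is None/k2=0)."""
    t = np.asarray(t, dtype=float)
    dt = t - t0
    after = t > t0
    out = np.full(t.shape, c + k + (k2 if lam2 is not None else 0.0))
    decay = k * np.exp(dt[after] * lam)
    if lam2 is not None:
        decay = decay + k2 * np.exp(dt[after] * lam2)
    out[after] = c + decay
    return out


@dataclass
class ExpFitResult:
    """Fitted onset-exponential coefficients and derived time constants."""

    model_order: int
    c: float
    k: float
    lam: float
    t0: float
    rss: float
    k2: float | None = None
    lam2: float | None = None
    tau_fast_ms: float | None = None
    tau_slow_ms: float | None = None
    frac_fast: float | None = None
    degenerate: bool = False
    n_samples: int = 0
    noise_sd: float = float("nan")

    def summary(self) -> str:
        lines = [f"Onset-exponential fit (order {self.model_order})",
                 f"  n = {self.n_samples}, RSS = {self.rss:.6g}",
                 f"  plateau c = {self.c:.6g}",
                 f"  onset t0 = {self.t0 * 1e3:.4g} ms"]
        if self.degenerate:
            lines.append("  DEGENERATE: amplitude below noise floor; "
                         "time constants undefined")
            return "\n".join(lines)
        lines.append(f"  tau_fast = {self.tau_fast_ms:.4g} ms")
        if self.tau_slow_ms is not None:
            lines.append(f"  tau_slow = {self.tau_slow_ms:.4g} ms")
            lines.append(f"  fraction fast = {self.frac_fast:.4g} %")
        return "\n".join(lines)


def downsample(trace: Trace, target_rate: float) -> Trace:
    """Block-mean decimation to ``target_rate`` (integer factor required)."""
    factor = trace.rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"rate {trace.rate} not an integer multiple of {target_rate}")
    factor = int(round(factor))
    n = (trace.n // factor) * factor
    vals = trace.values[:n].reshape(-1, factor).mean(axis=1)
    # block mean represents the center of each block
    return Trace(vals, target_rate,
                 t0_offset=trace.t0_offset + (factor - 1) / (2 * trace.rate),
                 units=trace.units, polarity=trace.polarity)


def correct_baseline_bleach(trace: Trace,
                            baseline_windows: list[tuple[float, float]],
                            n_terms: int = 3) -> Trace:
    """Divisive photobleaching correction fitted on baseline windows only.

    A three-term exponential trend is fitted on the samples inside
    ``baseline_windows`` (times in seconds; e.g. the holding periods at
    −70 mV) and the whole trace is divided by the evaluated trend.
    """
    from .screening import detrend_divide, fit_trend

    t = trace.times
    keep = np.zeros(trace.n, dtype=bool)
    for a, b in baseline_windows:
        keep |= (t >= a) & (t < b)
    if keep.sum() < 0.1 * trace.n:
        raise ValueError("baseline windows cover less than 10% of the record")
    exclude = ~keep
    trend = fit_trend(trace, exclude_mask=exclude, n_terms=n_terms)
    return detrend_divide(trace, trend)


def _design(t: np.ndarray, t0: float, lams: np.ndarray) -> np.ndarray:
    """Basis matrix [1, E_i(t)] with E_i = exp((t−t0)λ_i) past t0, else 1."""
    cols = [np.ones_like(t)]
    dt = t - t0
    after = t > t0
    for lam in lams:
        e = np.ones_like(t)
        e[after] = np.exp(dt[after] * lam)
        cols.append(e)
    return np.column_stack(cols)


def _solve_amplitudes(t: np.ndarray, f: np.ndarray, t0: float,
                      lams: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = _design(t, t0, lams)
    coef, *_ = np.linalg.lstsq(a, f, rcond=None)
    return coef, f - a @ coef


def fit_exp_onset(trace: Trace, window: tuple[float, float] | None = None,
                  model_order: int = 2, nominal_onset: float | None = None,
                  t0_halfwidth: float = 0.010, n_t0: int = 11,
                  amplitude_floor_mult: float = 3.0) -> ExpFitResult:
    """Fit the onset-exponential model by multi-start nonlinear least squares.

    Parameters
    ----------
    trace : Trace
        Bleach-corrected step response; conventionally cropped from 0.1 s
        before the nominal transition onset to 1 s after it (pass ``window``
        to crop here).
    window : (start, stop), optional
        Absolute-time crop applied before fitting.
    model_order : {1, 2}
        Mono- or dual-exponential relaxation.
    nominal_onset : float, optional
        Center of the onset multi-start grid; defaults to the time of the
        largest single-sample jump in the trace.
    t0_halfwidth, n_t0
        The onset grid spans ``nominal_onset ± t0_halfwidth`` seconds with
        ``n_t0`` starts; ``t0`` is then refined jointly with the rates.
    amplitude_floor_mult
        Fits whose total amplitude is below this multiple of the residual
        noise are flagged degenerate (time constants undefined).
    """
    if model_order not in (1, 2):
        raise ValueError("model_order must be 1 or 2")
    if window is not None:
        trace = trace.slice_time(*window)
    t = trace.times
    f = trace.values
    if trace.n < 10 * (2 + model_order):
        raise ValueError("trace too short for a stable fit")

    if nominal_onset is None:
        jumps = np.abs(np.diff(f))
        nominal_onset = float(t[int(np.argmax(jumps))])
    t_lo, t_hi = float(t[0]), float(t[-1])
    span = t_hi - t_lo

    # multi-start grids: onset times and log-spaced time constants
    t0_grid = np.clip(np.linspace(nominal_onset - t0_halfwidth,
                                  nominal_onset + t0_halfwidth, n_t0),
                      t_lo, t_hi - 1e-9)
    if model_order == 1:
        tau_starts = [(3e-4,), (3e-3,), (3e-2,)]
    else:
        tau_starts = [(3e-4, 1e-2), (1e-3, 3e-2), (5e-4, 5e-3)]

    log_rate_bounds = (np.log(1.0), np.log(1e7))   # tau from 100 ns to 1 s
    lo = [t_lo] + [log_rate_bounds[0]] * model_order
    hi = [t_hi] + [log_rate_bounds[1]] * model_order
    x_scale = [max(span / 100, 1e-4)] + [1.0] * model_order

    def make_residual(tt: np.ndarray, ff: np.ndarray):
        def residual(x: np.ndarray) -> np.ndarray:
            return _solve_amplitudes(tt, ff, x[0], -np.exp(x[1:]))[1]
        return residual

    # phase 1: multi-start on decimated samples (cheap); phase 2: polish
    # the best start on the full-resolution data
    stride = max(trace.n // 4000, 1)
    res_coarse = make_residual(t[::stride], f[::stride])
    best: tuple[float, np.ndarray] | None = None
    for t0_start in t0_grid:
        for taus in tau_starts:
            x0 = np.concatenate([[t0_start],
                                 [np.log(1.0 / tau) for tau in taus]])
            try:
                sol = least_squares(res_coarse, x0, bounds=(lo, hi),
                                    method="trf", max_nfev=60,
                                    x_scale=x_scale)
            except Exception:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError("onset-exponential fit failed to converge")

    sol = least_squares(make_residual(t, f), best[1], bounds=(lo, hi),
                        method="trf", max_nfev=200, x_scale=x_scale)
    rss, x = float(np.sum(sol.fun ** 2)), sol.x
    t0 = float(x[0])
    lams = -np.exp(x[1:])
    coef, resid = _solve_amplitudes(t, f, t0, lams)
    c = float(coef[0])
    amps = coef[1:]
    dof = max(trace.n - (2 + 2 * model_order), 1)
    noise_sd = float(np.sqrt(rss / dof))

    if model_order == 1:
        res = ExpFitResult(model_order=1, c=c, k=float(amps[0]),
                           lam=float(lams[0]), t0=t0, rss=rss,
                           n_samples=trace.n, noise_sd=noise_sd)
        total_amp = abs(res.k)
    else:
        # order components fast-first (more negative lambda = faster)
        order = np.argsort(lams)      # ascending: most negative first
        lams = lams[order]
        amps = amps[order]
        res = ExpFitResult(model_order=2, c=c, k=float(amps[0]),
                           lam=float(lams[0]), k2=float(amps[1]),
                           lam2=float(lams[1]), t0=t0, rss=rss,
                           n_samples=trace.n, noise_sd=noise_sd)
        total_amp = abs(res.k) + abs(res.k2)

    if total_amp < amplitude_floor_mult * noise_sd:
        res.degenerate = True
        return res
    _populate_taus(res)
    return res


def _populate_taus(res: ExpFitResult) -> None:
    tau1 = -1000.0 / res.lam
    if res.model_order == 1:
        res.tau_fast_ms = tau1
        return
    tau2 = -1000.0 / res.lam2
    if tau1 <= tau2:
        res.tau_fast_ms, res.tau_slow_ms = tau1, tau2
        k_fast, k_slow = res.k, res.k2
    else:
        res.tau_fast_ms, res.tau_slow_ms = tau2, tau1
        k_fast, k_slow = res.k2, res.k
    denom = abs(k_fast) + abs(k_slow)
    res.frac_fast = 100.0 * abs(k_fast) / denom if denom > 0 else float("nan")


def summarize_time_constants(fit: ExpFitResult) -> dict:
    """Report τ_fast (ms), τ_slow (ms or None) and fraction fast (% or None).

    Mono fits report only τ_fast; dual fits are labeled so τ_fast ≤ τ_slow.
    """
    if fit.degenerate:
        raise ValueError("degenerate fit: time constants undefined")
    return {"tau_fast_ms": fit.tau_fast_ms,
            "tau_slow_ms": fit.tau_slow_ms,
            "frac_fast": fit.frac_fast}


def select_model(trace: Trace, window: tuple[float, float] | None = None,
                 **fit_kw) -> int:
    """Choose mono vs dual model by corrected AIC plus an amplitude floor.

    The dual model wins only if it improves the small-sample-corrected AIC
    *and* both of its component amplitudes exceed three times the residual
    noise level; otherwise the mono model is kept (parsimony).
    """
    fit1 = fit_exp_onset(trace, window=window, model_order=1, **fit_kw)
    fit2 = fit_exp_onset(trace, window=window, model_order=2, **fit_kw)

    def aicc(rss: float, n: int, p: int) -> float:
        return n * np.log(max(rss, 1e-300) / n) + 2 * p \
            + 2 * p * (p + 1) / max(n - p - 1, 1)

    n = fit1.n_samples
    a1 = aicc(fit1.rss, n, 4)
    a2 = aicc(fit2.rss, n, 6)
    floor = 3.0 * fit2.noise_sd
    if a2 < a1 and abs(fit2.k) >= floor and abs(fit2.k2) >= floor:
        return 2
    return 1
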
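"""Exponential rise/decay fitting and sweep alignment.

Decays are modeled as ``y(t) = y_peak * exp(-t / tau_decay)`` with t
measured from the peak; rises as the saturating form
``y(t) = A * (1 - exp(-(t - t0) / tau_rise))`` between the detected
onset (last pre-peak frame at or below 10% of the peak amplitude) and
the peak.  Fits are unweighted nonlinear least squares via the
Levenberg-Marquardt implementation in :func:`scipy.optimize.curve_fit`,
initialized from the log-linear closed form, capped at 200 iterations.

A benchmark-mode rate-form fit (``dF/F = A0 * exp(b t)`` with t in
seconds, ``tau = 1000 / (-b)`` ms) and first-rise sweep alignment and
averaging round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .model import CaEvent, NormalizedTrace

__all__ = [
    "FitResult",
    "fit_decay",
    "fit_rise",
    "fit_decay_rate_form",
    "align_and_average",
]

_MAXFEV = 200  # iteration cap for LM


@dataclass
class FitResult:
    """Outcome of one exponential fit.

    ``tau`` is in ms (positive when converged), ``amplitude`` the fitted
    A or A0 in the trace's units, ``t0`` the ms time the fit is
    referenced to, ``rss`` the residual sum of squares over ``n_points``
    samples.
    """

    tau: Optional[float]
    amplitude: Optional[float]
    t0: float
    rss: float
    n_points: int
    converged: bool
    note: str = ""


def _log_linear_decay(t: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Closed-form (amplitude, tau) from a log-linear regression.

    Stray non-positive samples (noise near zero) are ignored; returns
    None when fewer than 2 positive samples remain or the segment is not
    decaying (slope >= 0), in which case LM has nothing sane to start
    from."""
    pos = y > 0
    if pos.sum() < 2:
        return None
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    if slope >= 0:
        return None
    return float(np.exp(intercept)), float(-1.0 / slope)


def fit_decay(
    trace: NormalizedTrace,
    event: CaEvent,
    fit_span: Optional[float] = None,
    cap_ms: float = 1000.0,
) -> FitResult:
    """Fit the post-peak decay ``y = y_peak * exp(-t / tau)``.

    The fitted window starts at the peak and, by default, ends where the
    trace first falls below 10% of the peak amplitude (capped at
    ``cap_ms``); an explicit ``fit_span`` in ms overrides that rule.
    On success the event's ``tau_decay`` and ``fit_rss`` are updated.
    """
    values = trace.values
    times = trace.times
    peak = event.peak_index
    peak_value = values[peak]
    dt = trace.meta.frame_interval

    if fit_span is not None:
        end = min(values.size, peak + int(round(fit_span / dt)) + 1)
    else:
        # fit up to (exclusive) the first sample below 10% of the peak
        end = values.size
        below = np.flatnonzero(values[peak:] < 0.1 * peak_value)
        if below.size:
            end = min(end, peak + int(below[0]))
        end = min(end, peak + int(round(cap_ms / dt)) + 1)

    t = times[peak:end] - times[peak]
    y = values[peak:end]
    if t.size < 3:
        raise ValueError(
            f"decay fit needs >= 3 samples from the peak, got {t.size}"
        )

    init = _log_linear_decay(t, y)
    if init is None:
        return FitResult(
            tau=None,
            amplitude=None,
            t0=float(times[peak]),
            rss=float(np.sum((y - y.mean()) ** 2)),
            n_points=t.size,
            converged=False,
            note="segment is not a positive decaying exponential",
        )
    try:
        popt, _ = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            t,
            y,
            p0=init,
            maxfev=_MAXFEV,
        )
    except RuntimeError:
        return FitResult(
            tau=None,
            amplitude=None,
            t0=float(times[peak]),
            rss=float("nan"),
            n_points=t.size,
            converged=False,
            note="LM did not converge",
        )
    a, tau = float(popt[0]), float(popt[1])
    if tau <= 0:
        return FitResult(
            tau=None,
            amplitude=a,
            t0=float(times[peak]),
            rss=float("nan"),
            n_points=t.size,
            converged=False,
            note="non-positive tau",
        )
    rss = float(np.sum((y - a * np.exp(-t / tau)) ** 2))
    event.tau_decay = tau
    event.fit_rss = rss
    return FitResult(
        tau=tau,
        amplitude=a,
        t0=float(times[peak]),
        rss=rss,
        n_points=t.size,
        converged=True,
    )


def fit_rise(
    trace: NormalizedTrace,
    event: CaEvent,
    onset_fraction: float = 0.10,
) -> FitResult:
    """Fit the pre-peak rise ``y = A * (1 - exp(-(t - t0) / tau))``.

    The onset is the last frame before the peak at which the trace is at
    or below ``onset_fraction`` of the peak amplitude (the segment start
    if no such frame exists).  The rise foot ``t0`` is a free parameter,
    bounded to within one frame before the onset sample, because noise
    can place the detected onset a frame or two early and a fixed foot
    then degenerates the fit.  A rise spanning fewer than 3 frames is
    flagged unresolved: tau is reported as one frame interval (an upper
    bound) with ``converged=False``.  On success the event's
    ``tau_rise`` and ``onset_time`` are updated.
    """
    values = trace.values
    times = trace.times
    peak = event.peak_index
    peak_value = values[peak]
    dt = trace.meta.frame_interval

    below = np.flatnonzero(values[:peak] <= onset_fraction * peak_value)
    onset = int(below[-1]) if below.size else 0

    t = times[onset : peak + 1] - times[onset]
    y = values[onset : peak + 1]
    if t.size < 3:
        event.tau_rise = dt
        event.onset_time = float(times[onset])
        return FitResult(
            tau=dt,
            amplitude=float(peak_value),
            t0=float(times[onset]),
            rss=float("nan"),
            n_points=t.size,
            converged=False,
            note="unresolved rise: fewer than 3 samples; tau bounded by one frame",
        )

    def model(t, a, tau, t0):
        return a * (1.0 - np.exp(-np.maximum(t - t0, 0.0) / tau))

    p0 = (
        float(peak_value),
        max((times[peak] - times[onset]) / 3.0, dt / 10.0),
        0.0,
    )
    try:
        with warnings.catch_warnings():
            # a degenerate direction at the bound is reported via rss/converged
            warnings.simplefilter("ignore", category=Warning)
            popt, _ = curve_fit(
                model,
                t,
                y,
                p0=p0,
                bounds=([0.0, dt / 100.0, -dt], [np.inf, np.inf, float(t[-1])]),
                maxfev=2000,
            )
    except (RuntimeError, ValueError):
        return FitResult(
            tau=None,
            amplitude=None,
            t0=float(times[onset]),
            rss=float("nan"),
            n_points=t.size,
            converged=False,
            note="rise fit did not converge",
        )
    a, tau, foot = (float(popt[0]), float(popt[1]), float(popt[2]))
    rss = float(np.sum((y - model(t, a, tau, foot)) ** 2))
    event.tau_rise = tau
    event.onset_time = float(times[onset])
    return FitResult(
        tau=tau,
        amplitude=a,
        t0=float(times[onset]),
        rss=rss,
        n_points=t.size,
        converged=True,
    )


def fit_decay_rate_form(
    values: Sequence[float], times_s: Sequence[float]
) -> FitResult:
    """Benchmark-convention decay fit ``dF/F = A0 * exp(b t)``, t in seconds.

    Returns amplitude = A0 (the intercept at t = 0) and
    ``tau = 1000 / (-b)`` ms.  A fitted rate b >= 0 is an error: the
    segment is not decaying.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if y.size != t.size:
        raise ValueError("values and times_s must have equal length")
    if y.size < 3:
        raise ValueError("rate-form fit needs >= 3 samples")

    init = _log_linear_decay(t, y)
    p0 = (init[0], -1.0 / init[1]) if init else (float(y[0]), -1.0)
    popt, _ = curve_fit(
        lambda t, a0, b: a0 * np.exp(b * t), t, y, p0=p0, maxfev=_MAXFEV
    )
    a0, b = float(popt[0]), float(popt[1])
    if b >= 0:
        raise ValueError(f"non-decaying segment: fitted rate b = {b:.4g} >= 0")
    rss = float(np.sum((y - a0 * np.exp(b * t)) ** 2))
    return FitResult(
        tau=1000.0 / (-b),
        amplitude=a0,
        t0=0.0,
        rss=rss,
        n_points=y.size,
        converged=True,
    )


def first_rise_index(
    trace: NormalizedTrace,
    stimulus_time: float,
    rise_threshold: Optional[float] = None,
) -> Optional[int]:
    """First post-stimulus frame exceeding the rise threshold.

    The default threshold is twice the standard deviation of the
    pre-stimulus segment.  Returns None when no frame qualifies.
    """
    times = trace.times
    values = trace.values
    pre = values[times < stimulus_time]
    if rise_threshold is None:
        if pre.size < 2:
            raise ValueError("cannot derive a rise threshold: no pre-stimulus segment")
        rise_threshold = 2.0 * float(np.std(pre))
    post = np.flatnonzero((times >= stimulus_time) & (values > rise_threshold))
    return int(post[0]) if post.size else None


def align_and_average(
    sweeps: Sequence[NormalizedTrace],
    stimulus_times: Sequence[float],
    rise_threshold: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Align sweeps on their first post-stimulus rise and average them.

    Each sweep's first-rise frame (first post-stimulus sample exceeding
    the threshold; default 2 sd of that sweep's pre-stimulus segment) is
    shifted to sit half a frame interval after the stimulus, and the
    sweeps are averaged pointwise over their overlap.  Returns
    ``(rel_times_ms, mean_values, n_used)`` where ``rel_times_ms`` is
    relative to the stimulus, so the first-rise sample sits at +dt/2.
    Sweeps with no supra-threshold frame are excluded.
    """
    if not sweeps:
        raise ValueError("no sweeps given")
    if len(sweeps) != len(stimulus_times):
        raise ValueError("one stimulus time per sweep is required")
    dt = sweeps[0].meta.frame_interval

    anchored = []
    for sweep, t_stim in zip(sweeps, stimulus_times):
        idx = first_rise_index(sweep, t_stim, rise_threshold)
        if idx is None:
            continue  # excluded: no supra-threshold frame
        anchored.append((sweep.values, idx))
    if not anchored:
        raise ValueError("no sweep has a supra-threshold first rise")

    # overlap in frame offsets relative to each sweep's first-rise frame
    lo = max(-idx for _, idx in anchored)
    hi = min(v.size - idx for v, idx in anchored)
    offsets = np.arange(lo, hi)
    stack = np.stack([v[offsets + idx] for v, idx in anchored])
    rel_times = offsets * dt + dt / 2.0
    return rel_times, stack.mean(axis=0), len(anchored)
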
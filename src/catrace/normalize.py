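"""Baseline estimation and normalization of fluorescence traces.

Two normalizations are provided:

* single-channel dF/F, ``(F - F0) / F0`` with ``F0(t)`` a sliding-window
  percentile baseline (default: 101-point window, 30th percentile);
* ratiometric dR/R, where ``R(t) = F_signal(t) / F_ref(t)`` and ``R0(t)``
  is by default the mean of the lowest 10% of ratio values within each
  101-point window.

Benchmark-mode helpers implement the linear photobleach detrend fitted to
pre-stimulus window means and the constant rest-baseline normalization
``(F - F_rest) / F_rest``.

Window edges are truncated at the array ends: near the edges the window
simply contains fewer samples.  No padding or reflection is used, so no
fabricated data enters the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .model import NormalizedTrace, Recording, StimulusProtocol

__all__ = [
    "BaselineParams",
    "BleachFit",
    "sliding_baseline",
    "normalize_dff",
    "smooth_reference",
    "normalize_drr",
    "bleach_correct",
    "rest_normalize",
]


@dataclass(frozen=True)
class BaselineParams:
    """Sliding-window baseline settings.

    ``window`` is an odd frame count (the window is centered, spanning
    (window-1)/2 frames on each side).  ``method`` selects either a
    linear-interpolation percentile of the window values or the mean of
    the lowest ``fraction`` of them (at least one value, via ceiling).
    """

    window: int = 101
    method: str = "percentile"  # "percentile" | "lowest_fraction"
    percentile: float = 30.0
    fraction: float = 0.10
    edge_policy: str = "truncate"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.method not in ("percentile", "lowest_fraction"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.edge_policy != "truncate":
            raise ValueError("only edge_policy='truncate' is supported")


@dataclass(frozen=True)
class BleachFit:
    """OLS line fitted to pre-stimulus window means.

    ``slope`` is in intensity units per ms; ``window_means`` holds the
    (window center time ms, mean intensity) points used for the fit.
    """

    slope: float
    intercept: float
    window_means: tuple[tuple[float, float], ...]


def _window_stat(window_values: np.ndarray, params: BaselineParams) -> float:
    if params.method == "percentile":
        return float(np.percentile(window_values, params.percentile, method="linear"))
    m = window_values.size
    k = math.ceil(params.fraction * m)
    return float(np.mean(np.sort(window_values)[:k]))


def sliding_baseline(values: np.ndarray, params: BaselineParams) -> np.ndarray:
    """Time-varying baseline by a centered sliding-window statistic.

    For index k the window is frames [k - h, k + h] with h = (window-1)/2,
    clipped to the array; output has the input's length.  Interior
    (full-window) positions are computed vectorized; truncated edge
    windows fall back to a per-index computation.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain non-finite entries")
    n = values.size
    h = (params.window - 1) // 2
    out = np.empty(n)

    if n >= params.window:
        windows = sliding_window_view(values, params.window)
        if params.method == "percentile":
            out[h : n - h] = np.percentile(
                windows, params.percentile, axis=1, method="linear"
            )
        else:
            k = math.ceil(params.fraction * params.window)
            out[h : n - h] = np.mean(np.sort(windows, axis=1)[:, :k], axis=1)
        edge_idx = list(range(h)) + list(range(n - h, n))
    else:
        edge_idx = list(range(n))

    for i in edge_idx:
        lo = max(0, i - h)
        hi = min(n, i + h + 1)
        out[i] = _window_stat(values[lo:hi], params)
    return out


def normalize_dff(
    recording: Recording, params: BaselineParams | None = None
) -> NormalizedTrace:
    """Single-channel dF/F: ``(F - F0) / F0`` with a sliding baseline."""
    params = params or BaselineParams()
    baseline = sliding_baseline(recording.signal, params)
    nonpos = np.flatnonzero(baseline <= 0)
    if nonpos.size:
        raise ValueError(
            f"baseline is non-positive at frame {int(nonpos[0])}; "
            "dF/F is undefined there"
        )
    values = (recording.signal - baseline) / baseline
    return NormalizedTrace(
        meta=recording.meta,
        values=values,
        baseline=baseline,
        mode="dff",
        roi_id=recording.roi_id,
        params={
            "window": params.window,
            "method": params.method,
            "percentile": params.percentile,
            "fraction": params.fraction,
        },
    )


def smooth_reference(reference: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with windows truncated at the array ends.

    ``window = 1`` is the identity.  Even windows are accepted and span
    window//2 frames on each side minus the far edge, i.e. the window is
    [i - (window-1)//2, i + window//2].
    """
    if window < 1:
        raise ValueError(f"smoothing window must be >= 1, got {window}")
    reference = np.asarray(reference, dtype=float)
    if window == 1:
        return reference.copy()
    n = reference.size
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate(([0.0], np.cumsum(reference)))
    lo = np.maximum(0, np.arange(n) - left)
    hi = np.minimum(n, np.arange(n) + right + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def normalize_drr(
    recording: Recording,
    params: BaselineParams | None = None,
    smooth_window: int = 1,
) -> NormalizedTrace:
    """Ratiometric dR/R from a dual-channel recording.

    The reference is smoothed first (moving average), then
    ``R = signal / reference``; R0 comes from the sliding baseline with
    the lowest-fraction method (101-point window, lowest 10%) unless
    ``params`` overrides, and ``dR/R = (R - R0) / R0``.
    """
    if recording.reference is None:
        raise ValueError("dR/R requires a reference channel on the recording")
    params = params or BaselineParams(method="lowest_fraction")
    ref = smooth_reference(recording.reference, smooth_window)
    nonpos = np.flatnonzero(ref <= 0)
    if nonpos.size:
        raise ValueError(
            f"smoothed reference is non-positive at frame {int(nonpos[0])}"
        )
    ratio = recording.signal / ref
    baseline = sliding_baseline(ratio, params)
    nonpos = np.flatnonzero(baseline <= 0)
    if nonpos.size:
        raise ValueError(f"R0 is non-positive at frame {int(nonpos[0])}")
    values = (ratio - baseline) / baseline
    return NormalizedTrace(
        meta=recording.meta,
        values=values,
        baseline=baseline,
        mode="drr",
        roi_id=recording.roi_id,
        params={
            "window": params.window,
            "method": params.method,
            "percentile": params.percentile,
            "fraction": params.fraction,
            "smooth_window": smooth_window,
        },
    )


def bleach_correct(
    recording: Recording,
    protocol: StimulusProtocol,
    window_ms: float = 100.0,
    multiplicative: bool = False,
) -> tuple[Recording, BleachFit]:
    """Remove a linear photobleach trend estimated from pre-stimulus windows.

    The mean intensity in each window ``[t_stim - window_ms, t_stim)`` is
    regressed on the window-center time (OLS).  By default the fitted
    line is subtracted, anchored so the first window's mean is unchanged:
    ``F_corr(t) = F(t) - slope * (t - t_center_first)``.  With
    ``multiplicative=True`` the trace is divided by the fitted line
    normalized to 1 at the first window center instead.
    """
    times = recording.times
    stim_times = [t for t, _ in protocol.all_stimuli]
    centers, means = [], []
    for t_stim in stim_times:
        mask = (times >= t_stim - window_ms) & (times < t_stim)
        if not mask.any():
            raise ValueError(
                f"pre-stimulus window before stimulus at {t_stim} ms "
                "contains no frames"
            )
        centers.append(t_stim - window_ms / 2.0)
        means.append(float(recording.signal[mask].mean()))
    if len(centers) < 2:
        raise ValueError("bleach correction needs >= 2 pre-stimulus windows")

    slope, intercept = np.polyfit(centers, means, 1)
    fit = BleachFit(
        slope=float(slope),
        intercept=float(intercept),
        window_means=tuple(zip(centers, means)),
    )
    t0 = centers[0]
    if multiplicative:
        line = (intercept + slope * times) / (intercept + slope * t0)
        if np.any(line <= 0):
            raise ValueError("fitted bleach line crosses zero; cannot divide")
        corrected = recording.signal / line
    else:
        corrected = recording.signal - slope * (times - t0)
    return recording.with_signal(corrected), fit


def rest_normalize(
    recording: Recording,
    first_stim_time: float,
    rest_ms: float = 100.0,
) -> NormalizedTrace:
    """Constant-baseline dF/F against the mean of the pre-stimulus rest.

    ``F_rest`` is the mean fluorescence over the half-open window
    ``[first_stim_time - rest_ms, first_stim_time)``; frames exactly at
    the stimulus are excluded.
    """
    times = recording.times
    mask = (times >= first_stim_time - rest_ms) & (times < first_stim_time)
    if not mask.any():
        raise ValueError(
            f"rest window [{first_stim_time - rest_ms}, {first_stim_time}) ms "
            "contains no frames"
        )
    f_rest = float(recording.signal[mask].mean())
    if f_rest <= 0:
        raise ValueError(f"F_rest must be positive, got {f_rest}")
    values = (recording.signal - f_rest) / f_rest
    return NormalizedTrace(
        meta=recording.meta,
        values=values,
        baseline=np.full(recording.n_frames, f_rest),
        mode="dff",
        roi_id=recording.roi_id,
        params={"rest_ms": rest_ms, "first_stim_time": first_stim_time},
    )
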
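"""Automated peak detection on normalized traces.

Three tunable criteria control detection: a minimum peak value
(threshold), a minimum width at half of the peak's own height (frames),
and a minimum inter-peak distance (ms; among conflicting peaks the
larger is kept, ties going to the earlier one).  A manual nearest-peak
operation rescues events the automatic pass missed: it ignores the
threshold but still requires a local maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CaEvent, NormalizedTrace

__all__ = [
    "DetectionSettings",
    "detect_peaks",
    "nearest_peak",
    "measure_amplitude",
    "local_maxima",
]


@dataclass(frozen=True)
class DetectionSettings:
    """Peak-detection criteria.

    threshold : minimum peak value, in the trace's dF/F or dR/R units.
    min_width : minimum frames the trace stays above half the peak's
        height around the peak.
    min_distance : minimum inter-peak separation, ms.
    search_radius : window for manual nearest-peak selection, ms.
    """

    threshold: float = 0.1
    min_width: int = 1
    min_distance: float = 0.0
    search_radius: float = 200.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")
        if self.search_radius <= 0:
            raise ValueError("search_radius must be positive")


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima, plateaus resolved to their first frame.

    A local maximum rises strictly above the sample before it and falls
    strictly below after (possibly after a flat plateau).  Array
    endpoints are never maxima.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    peaks = []
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j < n - 1 and values[j + 1] == values[i]:
                j += 1
            if j < n - 1 and values[j + 1] < values[i]:
                peaks.append(i)  # first frame of the plateau
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def _width_at_half_height(values: np.ndarray, peak: int) -> int:
    """Contiguous frames around the peak at or above half the peak value."""
    half = values[peak] / 2.0
    lo = peak
    while lo > 0 and values[lo - 1] >= half:
        lo -= 1
    hi = peak
    n = values.size
    while hi < n - 1 and values[hi + 1] >= half:
        hi += 1
    return hi - lo + 1


def detect_peaks(
    trace: NormalizedTrace, settings: DetectionSettings
) -> list[CaEvent]:
    """Detect Ca2+ transients meeting all three criteria.

    Candidates are local maxima with value >= threshold and
    width-at-half-height >= min_width frames.  Among candidates closer
    than min_distance (ms) the larger survives (amplitude ties: the
    earlier).  Events return time-ordered with ``source='auto'``,
    amplitude measured from zero, and kinetics unfit.
    """
    if trace.mode not in ("dff", "drr"):
        raise ValueError("detect_peaks requires a normalized (dff/drr) trace")
    values = trace.values
    times = trace.times

    candidates = [
        p
        for p in local_maxima(values)
        if values[p] >= settings.threshold
        and _width_at_half_height(values, p) >= settings.min_width
    ]

    # larger-wins suppression of peaks closer than min_distance
    kept: list[int] = []
    if settings.min_distance > 0:
        for p in sorted(candidates, key=lambda p: (-values[p], times[p])):
            if all(abs(times[p] - times[q]) >= settings.min_distance for q in kept):
                kept.append(p)
    else:
        kept = list(candidates)

    events = [
        CaEvent(
            peak_index=int(p),
            peak_time=float(times[p]),
            amplitude=float(values[p]),
            source="auto",
        )
        for p in sorted(kept)
    ]
    return events


def nearest_peak(
    trace: NormalizedTrace, t_click: float, settings: DetectionSettings
) -> CaEvent:
    """Manually rescue the local maximum nearest in time to ``t_click``.

    The threshold is ignored (the point of manual rescue is recovering
    sub-threshold or suppressed events); a local maximum must still
    exist within ``settings.search_radius`` ms.  Exact distance ties go
    to the earlier peak.
    """
    times = trace.times
    if not times[0] <= t_click <= times[-1]:
        raise ValueError(
            f"t_click {t_click} ms is outside the trace span "
            f"[{times[0]}, {times[-1]}] ms"
        )
    peaks = local_maxima(trace.values)
    in_radius = [p for p in peaks if abs(times[p] - t_click) <= settings.search_radius]
    if not in_radius:
        raise ValueError(
            f"no local maximum within {settings.search_radius} ms of "
            f"{t_click} ms"
        )
    best = min(in_radius, key=lambda p: (abs(times[p] - t_click), times[p]))
    return CaEvent(
        peak_index=int(best),
        peak_time=float(times[best]),
        amplitude=float(trace.values[best]),
        source="manual",
    )


def measure_amplitude(
    trace: NormalizedTrace,
    event: CaEvent,
    mode: str = "from_zero",
    span_ms: float = 200.0,
) -> float:
    """Measure an event's amplitude in the trace's normalized units.

    ``from_zero`` returns the trace value at the peak (the baseline of a
    normalized trace is zero).  ``from_local_base`` subtracts the trace
    minimum over the ``span_ms`` window preceding the peak, which
    removes the pedestal left by an unresolved earlier event.
    """
    if not 0 <= event.peak_index < trace.n_frames:
        raise IndexError(f"peak_index {event.peak_index} out of bounds")
    peak_value = float(trace.values[event.peak_index])
    if mode == "from_zero":
        return peak_value
    if mode == "from_local_base":
        times = trace.times
        t_peak = times[event.peak_index]
        mask = (times >= t_peak - span_ms) & (times < t_peak)
        if not mask.any():
            return peak_value
        return peak_value - float(trace.values[mask].min())
    raise ValueError(f"unknown amplitude mode {mode!r}")
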
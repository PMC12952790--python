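"""Core domain types for fluorescence time-series analysis.

The whole package works in a single unit system: frames are 0-based
integers, times are milliseconds, and intensities are either raw
(arbitrary units) or normalized (dimensionless dF/F or dR/R).  Frame k of
a recording maps to ``start_time + k * frame_interval`` ms, with
``frame_interval = 1000 / frame_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "Recording",
    "NormalizedTrace",
    "StimulusProtocol",
    "CaEvent",
    "frames_to_ms",
]


def frames_to_ms(tau_frames: float, frame_rate: float) -> float:
    """Convert a duration in frames to milliseconds.

    ``frame_rate`` is in frames per second, so one frame lasts
    ``1000 / frame_rate`` ms.
    """
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be positive, got {frame_rate}")
    return tau_frames * (1000.0 / frame_rate)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition timing and channel bookkeeping.

    Parameters
    ----------
    frame_rate : float
        Frames per second (> 0).
    start_time : float
        Time of frame 0, ms.
    channel_names : tuple of str
        Labels for the signal channel and, optionally, the reference
        channel.
    """

    frame_rate: float
    start_time: float = 0.0
    channel_names: tuple[str, ...] = ("signal",)

    def __post_init__(self) -> None:
        if not np.isfinite(self.frame_rate) or self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")

    @property
    def frame_interval(self) -> float:
        """Milliseconds per frame (1000 / frame_rate)."""
        return 1000.0 / self.frame_rate

    def times(self, n_frames: int) -> np.ndarray:
        """Time axis in ms for ``n_frames`` frames starting at frame 0."""
        return self.start_time + np.arange(n_frames) * self.frame_interval

    def time_to_frame(self, t_ms: float) -> int:
        """Nearest frame index for a time in ms (clipping not applied)."""
        return int(round((t_ms - self.start_time) / self.frame_interval))


def _as_finite_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"{name} contains a non-finite value at frame {bad}")
    return arr


@dataclass
class Recording:
    """One ROI's fluorescence time series, optionally dual-channel.

    ``signal`` holds the Ca2+-sensitive channel, ``reference`` the
    optional Ca2+-insensitive fluorophore recorded from the same ROI.
    ``mode`` records whether values are raw intensities or already
    normalized ("raw" | "dff" | "drr").
    """

    meta: AcquisitionMeta
    roi_id: str
    signal: np.ndarray
    reference: Optional[np.ndarray] = None
    mode: str = "raw"

    def __post_init__(self) -> None:
        self.signal = _as_finite_array(self.signal, "signal")
        if self.signal.size < 2:
            raise ValueError("signal must contain at least 2 frames")
        if self.reference is not None:
            self.reference = _as_finite_array(self.reference, "reference")
            if self.reference.size != self.signal.size:
                raise ValueError(
                    "reference length "
                    f"{self.reference.size} != signal length {self.signal.size}"
                )
        if self.mode not in ("raw", "dff", "drr"):
            raise ValueError(f"mode must be raw|dff|drr, got {self.mode!r}")

    @property
    def n_frames(self) -> int:
        return self.signal.size

    @property
    def times(self) -> np.ndarray:
        return self.meta.times(self.n_frames)

    def with_signal(self, signal: np.ndarray) -> "Recording":
        return replace(self, signal=np.asarray(signal, dtype=float))


@dataclass
class NormalizedTrace:
    """A dF/F or dR/R trace together with the baseline that produced it.

    ``values[k] == (raw[k] - baseline[k]) / baseline[k]`` for the raw
    series the trace was derived from; the baseline is strictly positive
    wherever values are defined.
    """

    meta: AcquisitionMeta
    values: np.ndarray
    baseline: np.ndarray
    mode: str  # "dff" | "drr"
    roi_id: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _as_finite_array(self.values, "values")
        self.baseline = _as_finite_array(self.baseline, "baseline")
        if self.values.size != self.baseline.size:
            raise ValueError("values and baseline must have equal length")
        if self.mode not in ("dff", "drr"):
            raise ValueError(f"mode must be dff|drr, got {self.mode!r}")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.meta.times(self.n_frames)


@dataclass(frozen=True)
class ProtocolBlock:
    """One stimulation block: a label, its nominal frequency, and the
    explicit stimulus times in ms."""

    label: str
    frequency: float  # Hz
    stimulus_times: tuple[float, ...]

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_times)

    @property
    def inter_stimulus_interval(self) -> float:
        """Nominal inter-stimulus interval, ms."""
        return 1000.0 / self.frequency


@dataclass
class StimulusProtocol:
    """Ordered stimulation blocks driving partitioning and train analysis.

    Stimulus times must be strictly increasing within and across blocks;
    within a block the intervals must agree with the block frequency to
    within ``frame_tolerance_ms`` (one frame interval of the recording
    being analyzed is a natural choice).
    """

    blocks: list[ProtocolBlock]
    pulse_duration: float = 1.0  # ms, metadata only

    def __post_init__(self) -> None:
        last = -np.inf
        for block in self.blocks:
            for t in block.stimulus_times:
                if t <= last:
                    raise ValueError(
                        "stimulus times must be strictly increasing "
                        f"(block {block.label!r}, time {t} ms)"
                    )
                last = t

    def validate_intervals(self, frame_tolerance_ms: float) -> None:
        """Check that within-block intervals match 1000/frequency."""
        for block in self.blocks:
            expected = block.inter_stimulus_interval
            diffs = np.diff(block.stimulus_times)
            if diffs.size and np.any(np.abs(diffs - expected) > frame_tolerance_ms):
                raise ValueError(
                    f"block {block.label!r}: inter-stimulus intervals deviate "
                    f"from 1000/{block.frequency} Hz by more than "
                    f"{frame_tolerance_ms} ms"
                )

    @property
    def all_stimuli(self) -> list[tuple[float, str]]:
        """Flat (time_ms, block_label) list across blocks, time-ordered."""
        out: list[tuple[float, str]] = []
        for block in self.blocks:
            out.extend((t, block.label) for t in block.stimulus_times)
        return out

    @classmethod
    def from_block_specs(
        cls,
        specs: Sequence[dict],
        pulse_duration: float = 1.0,
    ) -> "StimulusProtocol":
        """Build a protocol from ``{label, frequency_hz, n_stimuli,
        first_stimulus_ms}`` dictionaries (the config-file form)."""
        blocks = []
        for s in specs:
            freq = float(s["frequency_hz"])
            n = int(s["n_stimuli"])
            t0 = float(s["first_stimulus_ms"])
            times = tuple(t0 + i * 1000.0 / freq for i in range(n))
            blocks.append(ProtocolBlock(str(s["label"]), freq, times))
        return cls(blocks=blocks, pulse_duration=pulse_duration)


@dataclass
class CaEvent:
    """One detected Ca2+ transient.

    Times are ms; ``amplitude`` is in the units of the normalized trace
    (dF/F or dR/R).  Kinetic fields stay ``None`` until a fit succeeds.
    ``source`` is "auto" for threshold detection and "manual" for
    nearest-peak rescue; ``label`` carries the stimulus-block assignment.
    """

    peak_index: int
    peak_time: float
    amplitude: float
    tau_rise: Optional[float] = None
    tau_decay: Optional[float] = None
    onset_time: Optional[float] = None
    fit_rss: Optional[float] = None
    source: str = "auto"
    label: str = "unassigned"

    def __post_init__(self) -> None:
        if self.tau_rise is not None and self.tau_rise <= 0:
            raise ValueError("tau_rise must be positive when defined")
        if self.tau_decay is not None and self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive when defined")
        if self.onset_time is not None and self.onset_time > self.peak_time:
            raise ValueError("onset_time must not exceed peak_time")
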
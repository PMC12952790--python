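"""Stimulus-block assignment of events and train summaries.

Events are attributed to the stimulation block of the nearest preceding
stimulus when the peak latency falls inside the latency window, with at
most one event per stimulus.  Train summaries quantify the first and
final responses of a stimulus train measured from the pre-train
baseline, their ratio (the facilitation index), and the post-train decay
time constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .detect import local_maxima
from .kinetics import fit_decay
from .model import CaEvent, NormalizedTrace, ProtocolBlock, StimulusProtocol

__all__ = ["TrainSummary", "partition_events", "train_summary"]


@dataclass
class TrainSummary:
    """Summary of one stimulus train.

    Amplitudes are measured from the pre-train baseline in the trace's
    normalized units; ``facilitation_index = final / first``;
    ``post_train_tau`` is the decay time constant (ms) fitted after the
    final transient.
    """

    first_amplitude: float
    final_amplitude: float
    facilitation_index: float
    post_train_tau: Optional[float]
    n_stimuli: int
    baseline: float


def partition_events(
    events: Sequence[CaEvent],
    protocol: StimulusProtocol,
    latency_window: float = 100.0,
) -> list[CaEvent]:
    """Label each event with the block of its evoking stimulus.

    An event belongs to the nearest preceding stimulus when its latency
    (peak_time - stimulus_time) lies in (0, latency_window] ms.  Each
    stimulus claims at most one event, the one nearest in latency;
    surplus or out-of-window events are labeled "unassigned".  The
    operation is idempotent and returns the same event objects.
    """
    stimuli = protocol.all_stimuli
    for e in events:
        e.label = "unassigned"
    if not stimuli:
        return list(events)

    stim_times = np.array([t for t, _ in stimuli])
    # candidate (latency, event, stimulus index), nearest preceding stimulus only
    claims: dict[int, tuple[float, CaEvent]] = {}
    for e in sorted(events, key=lambda e: e.peak_time):
        k = int(np.searchsorted(stim_times, e.peak_time, side="left")) - 1
        if k < 0:
            continue
        latency = e.peak_time - stim_times[k]
        if not 0 < latency <= latency_window:
            continue
        held = claims.get(k)
        if held is None or latency < held[0]:
            claims[k] = (latency, e)
    for k, (_, e) in claims.items():
        e.label = stimuli[k][1]
    return list(events)


def _peak_in_window(
    trace: NormalizedTrace, t_lo: float, t_hi: float
) -> Optional[int]:
    """Index of the largest local maximum with time in (t_lo, t_hi]."""
    times = trace.times
    peaks = local_maxima(trace.values)
    in_win = [p for p in peaks if t_lo < times[p] <= t_hi]
    if not in_win:
        return None
    return max(in_win, key=lambda p: trace.values[p])


def train_summary(
    trace: NormalizedTrace,
    train_block: ProtocolBlock,
    baseline_window: float = 100.0,
    decay_span: float = 1000.0,
) -> TrainSummary:
    """Summarize a stimulus train on a normalized trace.

    The baseline is the trace mean over ``baseline_window`` ms before
    the first stimulus.  The first response is the peak within one
    inter-stimulus interval after stimulus 1, the final response the
    peak within one interval after the last stimulus, both minus the
    baseline.  The post-train decay constant comes from a
    single-exponential fit over ``decay_span`` ms after the final peak.
    """
    if train_block.n_stimuli < 2:
        raise ValueError("train summary needs a block with >= 2 stimuli")
    times = trace.times
    values = trace.values
    isi = train_block.inter_stimulus_interval
    t_first = train_block.stimulus_times[0]
    t_last = train_block.stimulus_times[-1]

    pre = (times >= t_first - baseline_window) & (times < t_first)
    if not pre.any():
        raise ValueError("pre-train baseline window contains no frames")
    baseline = float(values[pre].mean())

    p_first = _peak_in_window(trace, t_first, t_first + isi)
    if p_first is None:
        raise ValueError("no detectable peak after the first stimulus")
    p_last = _peak_in_window(trace, t_last, t_last + isi)
    if p_last is None:
        raise ValueError("no detectable peak after the last stimulus")

    first_amplitude = float(values[p_first]) - baseline
    final_amplitude = float(values[p_last]) - baseline
    if first_amplitude <= 0:
        raise ValueError("first response amplitude is non-positive")

    final_event = CaEvent(
        peak_index=int(p_last),
        peak_time=float(times[p_last]),
        amplitude=final_amplitude,
    )
    try:
        decay = fit_decay(trace, final_event, fit_span=decay_span)
        post_tau = decay.tau if decay.converged else None
    except ValueError:
        post_tau = None

    return TrainSummary(
        first_amplitude=first_amplitude,
        final_amplitude=final_amplitude,
        facilitation_index=final_amplitude / first_amplitude,
        post_train_tau=post_tau,
        n_stimuli=train_block.n_stimuli,
        baseline=baseline,
    )
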
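"""Action-potential detection and elementary response measures.

The amplitude criterion for a valid action potential defaults to 0 mV: an
event is a maximal run of samples strictly above the criterion, timed at the
local maximum of the excursion.  Events closer than the dead time are merged
into the earlier event.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import SpikeTrain, Trace, register_result

__all__ = ["LatencyResult", "detect_spikes", "firing_rate",
           "first_spike_latency"]


@register_result
@dataclass
class LatencyResult:
    """First-spike latency from stimulus onset; latency is NaN if no spike."""

    latency: float
    spike_found: bool


def detect_spikes(trace: Trace, criterion: float = 0.0,
                  dead_time: float = 1.0) -> SpikeTrain:
    """Detect suprathreshold excursions in a voltage trace.

    Parameters
    ----------
    trace : voltage trace (mV)
    criterion : mV; samples must exceed this strictly to count.  Samples
        exactly at the criterion are subthreshold (deterministic tie-break).
    dead_time : ms; an event starting closer than this to the previous kept
        event is merged into it.

    Returns
    -------
    SpikeTrain with one spike per excursion, at the time of its maximum.
    """
    if trace.kind != "voltage":
        raise TypeError(f"detect_spikes requires a voltage trace, "
                        f"got kind {trace.kind!r}")
    v = trace.samples
    above = v > criterion
    if not above.any():
        return SpikeTrain(times=np.empty(0), record_duration=trace.duration)
    # run boundaries of the boolean mask
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, v.size]
    peak_times = []
    for s, e in zip(starts, ends):
        idx = s + int(np.argmax(v[s:e]))
        peak_times.append(trace.t0 + idx * trace.dt)
    kept = []
    for t in peak_times:
        if not kept or t - kept[-1] >= dead_time:
            kept.append(t)
    return SpikeTrain(times=np.array(kept), record_duration=trace.duration)


def firing_rate(train: SpikeTrain, window: tuple) -> float:
    """Spike count in [w0, w1) divided by window length, in spikes/s."""
    w0, w1 = float(window[0]), float(window[1])
    if not w1 > w0:
        raise ValueError(f"empty or inverted window {window}")
    if w0 < 0 or w1 > train.record_duration + 1e-9:
        raise ValueError(f"window {window} outside record "
                         f"[0, {train.record_duration}]")
    count = int(np.count_nonzero((train.times >= w0) & (train.times < w1)))
    return count / (w1 - w0) * 1000.0


def first_spike_latency(train: SpikeTrain, stim_onset: float) -> LatencyResult:
    """Latency of the first spike at or after stimulus onset, in ms."""
    after = train.times[train.times >= stim_onset]
    if after.size == 0:
        return LatencyResult(latency=float("nan"), spike_found=False)
    return LatencyResult(latency=float(after[0] - stim_onset),
                         spike_found=True)
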
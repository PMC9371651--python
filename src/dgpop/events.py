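"""Calcium-event detection from dF/F traces.

A deliberately simple onset detector for binarizing fluorescence traces:
candidate events start where the trace rises above
``median + threshold_factor x MAD`` (default 4 median absolute deviations);
a candidate is accepted only if, after the peak of its above-threshold
excursion, the trace stays above threshold for at least ``min_decay_s``
(default 0.2 s) — briefer excursions are treated as noise.  One event is
marked at each accepted onset frame.
"""

from __future__ import annotations

import warnings

import numpy as np

from dgpop.core import EventTrain

__all__ = ["detect_events"]


def detect_events(
    dff: np.ndarray,
    frame_rate: float,
    threshold_factor: float = 4.0,
    min_decay_s: float = 0.2,
    neuron_id: str = "n000",
) -> EventTrain:
    """Binarize a dF/F trace into an event train.

    Parameters
    ----------
    dff
        Fluorescence-change-ratio trace (finite values).
    frame_rate
        Sampling rate in Hz.
    threshold_factor
        Onset threshold in median absolute deviations above the median.
    min_decay_s
        Minimum post-peak above-threshold duration; faster decays are
        rejected.
    """
    dff = np.asarray(dff, dtype=float)
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if not np.all(np.isfinite(dff)):
        raise ValueError("dF/F trace contains non-finite values")
    events = np.zeros(len(dff), dtype=np.uint8)
    med = np.median(dff)
    mad = np.median(np.abs(dff - med))
    if mad == 0:
        warnings.warn("constant trace (MAD = 0): no events detected", RuntimeWarning)
        return EventTrain(neuron_id, events, frame_rate)
    thr = med + threshold_factor * mad
    above = dff > thr
    # contiguous above-threshold runs
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(dff)]
    dt = 1.0 / frame_rate
    for s, e in zip(starts, ends):
        peak = s + int(np.argmax(dff[s:e]))
        decay_s = (e - peak) * dt
        if decay_s >= min_decay_s:
            events[s] = 1
    return EventTrain(neuron_id, events, frame_rate)
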
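"""Per-neuron tuning summaries: spatial maps, speed and direction curves.

Spatial tuning maps are occupancy-normalized event-rate rasters on a fine
(default 1-cm) pixel grid, smoothed with a Gaussian kernel (sigma in cm,
default 2.0) and normalized to each neuron's maximum rate.  Smoothing is
occupancy-weighted — the smoothed rate is G*(rate x occupancy) / G*(occupancy)
with a reflecting boundary — so the occupancy-weighted mean rate is preserved
exactly (weights: smoothed occupancy).  Speed and direction tuning curves are
mean event rates within the three speed classes and the eight direction arcs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from dgpop.behavior import (
    N_DIRECTION_BINS,
    SPEED_CLASS_LABELS,
    BehavioralState,
)
from dgpop.core import Trajectory

__all__ = [
    "SpatialTuningMap",
    "SpeedTuningCurve",
    "DirectionTuningCurve",
    "spatial_tuning_map",
    "speed_tuning_curve",
    "direction_tuning_curve",
]


@dataclass
class SpatialTuningMap:
    """Occupancy-normalized, smoothed spatial event-rate map.

    ``rate_grid`` is the smoothed rate (events/s) per pixel; pixels never
    visited (even after smoothing) are NaN.  ``normalized_grid`` is
    ``rate_grid`` divided by its maximum (all-zero, with ``has_events``
    False, when the neuron fired no events).
    """

    rate_grid: np.ndarray
    raw_rate_grid: np.ndarray
    occupancy_grid: np.ndarray  # s per pixel (raw)
    smoothed_occupancy: np.ndarray
    normalized_grid: np.ndarray
    sigma: float  # cm
    pixel_size: float  # cm
    has_events: bool


@dataclass
class SpeedTuningCurve:
    """Mean event rate (events/s) in the three speed classes.

    ``rates`` is NaN (and ``defined`` False) for classes with zero occupancy.
    """

    rates: np.ndarray  # (3,)
    occupancy_s: np.ndarray
    defined: np.ndarray
    labels: tuple = SPEED_CLASS_LABELS


@dataclass
class DirectionTuningCurve:
    """Mean event rate per 8 motion-direction arcs (bin 0 = north)."""

    rates: np.ndarray  # (8,)
    occupancy_s: np.ndarray
    defined: np.ndarray
    normalized: np.ndarray = None

    def __post_init__(self):
        if self.normalized is None:
            finite = self.rates[np.isfinite(self.rates)]
            peak = finite.max() if finite.size and finite.max() > 0 else np.nan
            with np.errstate(invalid="ignore"):
                self.normalized = self.rates / peak


def spatial_tuning_map(
    events: np.ndarray,
    trajectory: Trajectory,
    sigma: float = 2.0,
    pixel_size: float = 1.0,
) -> SpatialTuningMap:
    """Build a smoothed, occupancy-normalized spatial event-rate map.

    Parameters
    ----------
    events
        Binary event train aligned to ``trajectory``.
    sigma
        Gaussian smoothing width in cm (0 disables smoothing).
    pixel_size
        Raster resolution in cm; sigma is meaningful on a raster finer than
        the smoothing scale (default 1-cm pixels).
    """
    events = np.asarray(events)
    if len(events) != trajectory.n_frames:
        raise ValueError("events/trajectory length mismatch")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    dt = trajectory.dt
    rows = max(int(np.ceil(trajectory.arena_height / pixel_size)), 1)
    cols = max(int(np.ceil(trajectory.arena_width / pixel_size)), 1)
    col = np.minimum((trajectory.x / pixel_size).astype(int), cols - 1)
    row = np.minimum((trajectory.y / pixel_size).astype(int), rows - 1)
    flat = row * cols + col
    occ = np.bincount(flat, minlength=rows * cols).reshape(rows, cols) * dt
    cnt = np.bincount(flat, weights=events, minlength=rows * cols).reshape(rows, cols)
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy")
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_rate = np.where(occ > 0, cnt / np.where(occ > 0, occ, 1.0), np.nan)
    if sigma > 0:
        spx = sigma / pixel_size
        num = gaussian_filter(cnt, spx, mode="reflect", truncate=3.0)
        den = gaussian_filter(occ, spx, mode="reflect", truncate=3.0)
    else:
        num, den = cnt, occ
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    has_events = bool(np.sum(events) > 0)
    finite = rate[np.isfinite(rate)]
    peak = finite.max() if finite.size else 0.0
    if has_events and peak > 0:
        normalized = rate / peak
    else:
        normalized = np.where(np.isfinite(rate), 0.0, np.nan)
    return SpatialTuningMap(
        rate_grid=rate,
        raw_rate_grid=raw_rate,
        occupancy_grid=occ,
        smoothed_occupancy=den,
        normalized_grid=normalized,
        sigma=sigma,
        pixel_size=pixel_size,
        has_events=has_events,
    )


def _class_curve(events, labels, n_classes, dt):
    occ = np.bincount(labels, minlength=n_classes).astype(float) * dt
    cnt = np.bincount(labels, weights=events, minlength=n_classes)
    defined = occ > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(defined, cnt / np.where(defined, occ, 1.0), np.nan)
    return rates, occ, defined


def speed_tuning_curve(events: np.ndarray, state: BehavioralState, dt: float) -> SpeedTuningCurve:
    """Mean event rate in each speed class (events in class / time in class)."""
    events = np.asarray(events)
    if len(events) != len(state.speed_class):
        raise ValueError("events/state length mismatch")
    rates, occ, defined = _class_curve(events, state.speed_class, 3, dt)
    return SpeedTuningCurve(rates=rates, occupancy_s=occ, defined=defined)


def direction_tuning_curve(
    events: np.ndarray, state: BehavioralState, dt: float
) -> DirectionTuningCurve:
    """Mean event rate per direction arc, over frames with defined direction."""
    events = np.asarray(events)
    if len(events) != len(state.direction_bin):
        raise ValueError("events/state length mismatch")
    ok = state.direction_bin >= 0
    rates, occ, defined = _class_curve(
        events[ok], state.direction_bin[ok], N_DIRECTION_BINS, dt
    )
    return DirectionTuningCurve(rates=rates, occupancy_s=occ, defined=defined)
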
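"""Kinematics and behavioral-state discretization.

Speed and motion direction are derived from frame-to-frame displacements of
the (optionally smoothed) position track.  Direction follows the north-zero
convention: 0 rad is north (+y), angles in (0, pi] point west of north and
angles in (-pi, 0) east of north, i.e. ``direction = atan2(-dx, dy)``.

Behavior is discretized into the three state spaces used downstream: an
equal-area occupancy grid over the arena, three speed classes
([0,1), [1,5), [5,inf) cm/s) and eight motion-direction arcs of width pi/4
centered on 0, +-pi/4, +-pi/2, +-3pi/4 and pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from dgpop.core import Trajectory

__all__ = [
    "KinematicSeries",
    "BehavioralState",
    "compute_kinematics",
    "discretize_states",
    "SPEED_CLASS_EDGES",
    "SPEED_CLASS_LABELS",
    "N_DIRECTION_BINS",
]

SPEED_CLASS_EDGES = (1.0, 5.0)  # cm/s; classes [0,1), [1,5), [5,inf)
SPEED_CLASS_LABELS = ("0-1 cm/s", "1-5 cm/s", ">5 cm/s")
N_DIRECTION_BINS = 8


@dataclass
class KinematicSeries:
    """Per-frame speed (cm/s) and motion direction (rad, north-zero).

    ``valid`` is False where the displacement is below the resolution
    threshold; direction is NaN there (angle undefined at zero displacement).
    """

    speed: np.ndarray
    direction: np.ndarray
    valid: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.speed)


@dataclass
class BehavioralState:
    """Discretized behavior per frame.

    position_row / position_col index the occupancy grid (row 0 at y=0,
    col 0 at x=0); ``speed_class`` is 0/1/2 for the three classes;
    ``direction_bin`` is 0..7 (0 = north, increasing toward west) and -1
    where direction is undefined.
    """

    position_row: np.ndarray
    position_col: np.ndarray
    speed_class: np.ndarray
    direction_bin: np.ndarray
    grid_shape: tuple

    @property
    def position_flat(self) -> np.ndarray:
        """Flat position-bin label per frame (row-major)."""
        return self.position_row * self.grid_shape[1] + self.position_col


def compute_kinematics(
    trajectory: Trajectory,
    smoothing_window: int = 3,
    min_displacement: float = 1e-6,
) -> KinematicSeries:
    """Derive speed and motion direction from a trajectory.

    Positions are smoothed with a centered moving average of
    ``smoothing_window`` frames (1 disables smoothing; default 3 frames = 1 s
    at 3 Hz, suppressing tracking jitter), then differentiated between
    consecutive frames.  The first frame inherits the speed/direction of the
    first displacement.

    Parameters
    ----------
    trajectory
        Position track with at least two frames.
    smoothing_window
        Centered moving-average width in frames (odd recommended).
    min_displacement
        Displacements (cm) below this are flagged invalid: direction is
        undefined at zero displacement.
    """
    if trajectory.n_frames < 2:
        raise ValueError("kinematics require at least 2 frames")
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    x, y = trajectory.x, trajectory.y
    if smoothing_window > 1:
        x = uniform_filter1d(x, size=smoothing_window, mode="nearest")
        y = uniform_filter1d(y, size=smoothing_window, mode="nearest")
    dx = np.diff(x)
    dy = np.diff(y)
    dt = np.diff(trajectory.frame_times)
    disp = np.hypot(dx, dy)
    speed = np.empty(trajectory.n_frames)
    speed[1:] = disp / dt
    speed[0] = speed[1]
    direction = np.full(trajectory.n_frames, np.nan)
    valid = np.empty(trajectory.n_frames, dtype=bool)
    valid[1:] = disp >= min_displacement
    valid[0] = valid[1]
    ang = np.arctan2(-dx, dy)  # north-zero, west-positive
    direction[1:] = np.where(valid[1:], ang, np.nan)
    direction[0] = direction[1]
    return KinematicSeries(speed=speed, direction=direction, valid=valid)


def discretize_states(
    kin: KinematicSeries,
    trajectory: Trajectory,
    grid: tuple = (10, 10),
) -> BehavioralState:
    """Map each frame to a position bin, speed class and direction bin.

    Position bins form an equal-area ``grid`` (rows x cols) over the arena
    with half-open cells (the last row/column closed at the far wall).
    """
    rows, cols = grid
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    if kin.n_frames != trajectory.n_frames:
        raise ValueError("kinematics/trajectory length mismatch")
    x, y = trajectory.x, trajectory.y
    if np.any(x < 0) or np.any(x > trajectory.arena_width) or np.any(y < 0) or np.any(
        y > trajectory.arena_height
    ):
        raise ValueError("trajectory frames outside the arena")
    col = np.minimum((x / trajectory.arena_width * cols).astype(int), cols - 1)
    row = np.minimum((y / trajectory.arena_height * rows).astype(int), rows - 1)
    speed_class = np.digitize(kin.speed, SPEED_CLASS_EDGES)
    direction_bin = np.full(kin.n_frames, -1, dtype=int)
    ok = kin.valid & np.isfinite(kin.direction)
    # arcs of width pi/4 centered on multiples of pi/4; bin 0 = north
    direction_bin[ok] = (
        np.round(kin.direction[ok] / (np.pi / 4)).astype(int) % N_DIRECTION_BINS
    )
    return BehavioralState(
        position_row=row,
        position_col=col,
        speed_class=speed_class,
        direction_bin=direction_bin,
        grid_shape=(rows, cols),
    )
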
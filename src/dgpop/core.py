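"""Core data containers shared across the analysis pipeline.

Conventions (used throughout the package):

* lengths in cm, times in seconds, rates in events/s (Hz);
* angles in radians in (-pi, pi], with north (the +y axis) at 0 and angles
  increasing toward west (the -x axis), i.e. direction = atan2(-dx, dy);
* event trains are binary (0/1) vectors sampled at the recording frame rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TuningSpec",
    "EventTrain",
    "PopulationRecording",
    "TMazeSession",
]


@dataclass
class Trajectory:
    """A time-stamped 2-D position track at a fixed frame rate.

    Positions are in cm within an arena spanning
    ``[0, arena_width] x [0, arena_height]``; x increases east, y north.
    """

    frame_times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_width: float
    arena_height: float

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frame_times) == len(self.x) == len(self.y)):
            raise ValueError("frame_times, x and y must have equal length")
        if len(self.frame_times) >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        eps = 1e-9
        if np.any(self.x < -eps) or np.any(self.x > self.arena_width + eps):
            raise ValueError("x positions outside [0, arena_width]")
        if np.any(self.y < -eps) or np.any(self.y > self.arena_height + eps):
            raise ValueError("y positions outside [0, arena_height]")
        np.clip(self.x, 0.0, self.arena_width, out=self.x)
        np.clip(self.y, 0.0, self.arena_height, out=self.y)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def frame_rate(self) -> float:
        dts = np.diff(self.frame_times)
        return 1.0 / float(np.mean(dts))

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class TuningSpec:
    """Per-neuron tuning parameters for the synthetic event generator.

    Each field is an array of length ``n_neurons``:

    baseline_rate
        mean event rate in events/s (the generator normalizes modulation
        factors to unit occupancy mean, so this *is* the expected rate).
    place_center, place_width, place_gain
        Gaussian place-field bump: factor ``1 + gain * exp(-d^2 / 2 width^2)``.
    speed_slope
        multiplicative linear speed ramp per (cm/s) around the session mean
        speed, floored at 0.
    direction_pref, direction_concentration
        von Mises-shaped direction factor with unit circular mean.
    lr_arm_gain / lr_arm_pref, lr_decision_gain / lr_decision_pref
        differential T-maze modulation ``1 + gain * pref * side`` in the
        forced-arm and decision windows (side: L=+1, R=-1; pref in {-1,+1}).
    """

    baseline_rate: np.ndarray
    place_center: np.ndarray  # (n, 2) cm
    place_width: np.ndarray  # cm
    place_gain: np.ndarray
    speed_slope: np.ndarray  # 1/(cm/s)
    direction_pref: np.ndarray  # rad in (-pi, pi]
    direction_concentration: np.ndarray
    lr_arm_gain: np.ndarray = None
    lr_arm_pref: np.ndarray = None
    lr_decision_gain: np.ndarray = None
    lr_decision_pref: np.ndarray = None
    structure_label: str = "independent"

    def __post_init__(self) -> None:
        n = self.n_neurons
        for name in ("lr_arm_gain", "lr_decision_gain"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n))
        for name in ("lr_arm_pref", "lr_decision_pref"):
            if getattr(self, name) is None:
                setattr(self, name, np.ones(n))
        if np.any(np.asarray(self.baseline_rate) < 0):
            raise ValueError("baseline_rate must be nonnegative")
        pref = np.asarray(self.direction_pref, dtype=float)
        if np.any(pref <= -np.pi - 1e-12) or np.any(pref > np.pi + 1e-12):
            raise ValueError("direction_pref must lie in (-pi, pi]")

    @property
    def n_neurons(self) -> int:
        return len(np.atleast_1d(self.baseline_rate))

    def subset(self, idx) -> "TuningSpec":
        """Spec restricted to the neurons in ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return TuningSpec(
            baseline_rate=np.asarray(self.baseline_rate)[idx],
            place_center=np.asarray(self.place_center)[idx],
            place_width=np.asarray(self.place_width)[idx],
            place_gain=np.asarray(self.place_gain)[idx],
            speed_slope=np.asarray(self.speed_slope)[idx],
            direction_pref=np.asarray(self.direction_pref)[idx],
            direction_concentration=np.asarray(self.direction_concentration)[idx],
            lr_arm_gain=np.asarray(self.lr_arm_gain)[idx],
            lr_arm_pref=np.asarray(self.lr_arm_pref)[idx],
            lr_decision_gain=np.asarray(self.lr_decision_gain)[idx],
            lr_decision_pref=np.asarray(self.lr_decision_pref)[idx],
            structure_label=self.structure_label,
        )

    def to_json(self, path) -> None:
        payload = {
            "structure_label": self.structure_label,
            "baseline_rate": np.asarray(self.baseline_rate).tolist(),
            "place_center": np.asarray(self.place_center).tolist(),
            "place_width": np.asarray(self.place_width).tolist(),
            "place_gain": np.asarray(self.place_gain).tolist(),
            "speed_slope": np.asarray(self.speed_slope).tolist(),
            "direction_pref": np.asarray(self.direction_pref).tolist(),
            "direction_concentration": np.asarray(
                self.direction_concentration
            ).tolist(),
            "lr_arm_gain": np.asarray(self.lr_arm_gain).tolist(),
            "lr_arm_pref": np.asarray(self.lr_arm_pref).tolist(),
            "lr_decision_gain": np.asarray(self.lr_decision_gain).tolist(),
            "lr_decision_pref": np.asarray(self.lr_decision_pref).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TuningSpec":
        with open(path) as fh:
            payload = json.load(fh)
        label = payload.pop("structure_label")
        arrays = {k: np.asarray(v, dtype=float) for k, v in payload.items()}
        return cls(structure_label=label, **arrays)


@dataclass
class EventTrain:
    """One neuron's binarized event train at the recording frame rate."""

    neuron_id: str
    events: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events)
        vals = np.unique(self.events)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"event train {self.neuron_id!r} is not binary")
        self.events = self.events.astype(np.uint8)


@dataclass
class PopulationRecording:
    """Frame-aligned binary event trains for a recorded population.

    ``events`` is a (n_frames, n_neurons) 0/1 matrix; columns follow
    ``neuron_ids``.
    """

    events: np.ndarray
    neuron_ids: list
    frame_rate: float

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events)
        if self.events.ndim != 2:
            raise ValueError("events must be a (n_frames, n_neurons) matrix")
        if not np.all(np.isin(np.unique(self.events), [0, 1])):
            raise ValueError("event values must be 0 or 1")
        self.events = self.events.astype(np.uint8)
        self.neuron_ids = list(self.neuron_ids)
        if len(self.neuron_ids) != self.events.shape[1]:
            raise ValueError("neuron_ids length must match event columns")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron IDs must be unique")

    @property
    def n_frames(self) -> int:
        return self.events.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.events.shape[1]

    def train(self, i: int) -> EventTrain:
        return EventTrain(self.neuron_ids[i], self.events[:, i], self.frame_rate)

    def subset(self, idx) -> "PopulationRecording":
        idx = np.asarray(idx)
        return PopulationRecording(
            self.events[:, idx],
            [self.neuron_ids[i] for i in idx],
            self.frame_rate,
        )


@dataclass
class TMazeSession:
    """A forced-alternation T-maze session.

    ``trials`` has one row per trial with columns ``trial_id``,
    ``forced_side`` ('L'/'R'), ``free_choice`` ('L'/'R'), ``correct`` (bool),
    ``forced_turn_time_s`` and ``free_choice_turn_time_s`` (absolute session
    time).  A trial is correct iff the free choice differs from the forced
    side (the forced-alternation rule).
    """

    trials: pd.DataFrame
    trajectory: Trajectory
    recording: PopulationRecording = None

    def __post_init__(self) -> None:
        required = {
            "trial_id",
            "forced_side",
            "free_choice",
            "correct",
            "forced_turn_time_s",
            "free_choice_turn_time_s",
        }
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        expect = self.trials["free_choice"] != self.trials["forced_side"]
        if not (self.trials["correct"].astype(bool) == expect).all():
            raise ValueError("correct flag inconsistent with alternation rule")
        if self.recording is not None:
            if self.recording.n_frames != self.trajectory.n_frames:
                raise ValueError("recording/trajectory frame count mismatch")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def frame_rate(self) -> float:
        return self.trajectory.frame_rate
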
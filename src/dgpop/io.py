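"""CSV interchange formats and run manifests.

All files are plain CSV.  Conventions stated once here and in every header
comment: lengths in cm, times in seconds, angles in radians (north-zero,
west-positive, range (-pi, pi]), event values 0/1.

* trajectory CSV — columns ``time_s, x_cm, y_cm``; a leading comment line
  records the arena dimensions.
* events CSV — frames x neurons 0/1 matrix, header row of unique neuron IDs.
* trials CSV — ``trial_id, forced_side, free_choice, correct,
  forced_turn_time_s, free_choice_turn_time_s``.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from dgpop.core import PopulationRecording, TMazeSession, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_events",
    "read_events",
    "write_trials",
    "read_trials",
    "read_recording",
    "write_manifest",
]

_UNITS_NOTE = "units: cm, s, radians (north-zero, west-positive, (-pi, pi])"


class SchemaError(ValueError):
    """A file does not conform to the package CSV schemas."""


def write_trajectory(trajectory: Trajectory, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# arena_width_cm={trajectory.arena_width} "
            f"arena_height_cm={trajectory.arena_height} ; {_UNITS_NOTE}\n"
        )
        pd.DataFrame(
            {
                "time_s": trajectory.frame_times,
                "x_cm": trajectory.x,
                "y_cm": trajectory.y,
            }
        ).to_csv(fh, index=False)


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    arena = {}
    if first.startswith("#"):
        for token in first[1:].split(";")[0].split():
            if "=" in token:
                key, val = token.split("=", 1)
                arena[key] = float(val)
    else:
        raise SchemaError("trajectory CSV missing arena header comment")
    df = pd.read_csv(path, comment="#")
    missing = {"time_s", "x_cm", "y_cm"} - set(df.columns)
    if missing:
        raise SchemaError(f"trajectory CSV missing columns: {sorted(missing)}")
    return Trajectory(
        df["time_s"].to_numpy(),
        df["x_cm"].to_numpy(),
        df["y_cm"].to_numpy(),
        arena_width=arena["arena_width_cm"],
        arena_height=arena["arena_height_cm"],
    )


def write_events(recording: PopulationRecording, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={recording.frame_rate} ; values 0/1\n")
        pd.DataFrame(recording.events, columns=recording.neuron_ids).to_csv(
            fh, index=False
        )


def read_events(path, frame_rate: float = None) -> PopulationRecording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split(";")[0].split():
            if token.startswith("frame_rate_hz="):
                frame_rate = float(token.split("=", 1)[1])
    if frame_rate is None:
        raise SchemaError("events CSV missing frame_rate_hz header and no rate given")
    df = pd.read_csv(path, comment="#")
    ids = list(df.columns)
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate neuron IDs in events CSV header")
    values = df.to_numpy()
    bad = ~np.isin(values, [0, 1])
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise SchemaError(
            f"non-binary event value {values[r, c]!r} at row {r}, column {ids[c]!r}"
        )
    return PopulationRecording(values, ids, frame_rate)


_TRIAL_COLUMNS = [
    "trial_id",
    "forced_side",
    "free_choice",
    "correct",
    "forced_turn_time_s",
    "free_choice_turn_time_s",
]


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[_TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"trial CSV missing columns: {sorted(missing)}")
    for col in ("forced_side", "free_choice"):
        bad = ~df[col].isin(["L", "R"])
        if bad.any():
            raise SchemaError(f"invalid side label in column {col!r}")
    df["correct"] = df["correct"].astype(bool)
    return df


def read_recording(
    events_path, trajectory_path=None, trials_path=None
):
    """Load an aligned recording; returns (recording, trajectory[, session]).

    Alignment (equal frame counts) is validated at load; with a trial table a
    full :class:`TMazeSession` is returned instead of the bare pair.
    """
    recording = read_events(events_path)
    trajectory = None
    if trajectory_path is not None:
        trajectory = read_trajectory(trajectory_path)
        if trajectory.n_frames != recording.n_frames:
            raise SchemaError(
                f"alignment error: trajectory has {trajectory.n_frames} frames, "
                f"events {recording.n_frames}"
            )
    if trials_path is not None:
        if trajectory is None:
            raise SchemaError("a trial table requires a trajectory for alignment")
        trials = read_trials(trials_path)
        return TMazeSession(trials=trials, trajectory=trajectory, recording=recording)
    return recording, trajectory


def write_manifest(out_dir, command: str, config: dict, seed) -> Path:
    """Write a machine-readable run manifest (config, seed, version)."""
    from dgpop import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return path
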
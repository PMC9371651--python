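"""Synthetic recordings with the statistical structure the analysis assumes.

The generator emulates miniscope recordings of sparsely active hippocampal
granule cells: ~30-min open-field (OF) sessions sampled at 3 Hz, ~70 neurons
per animal with mean calcium-event rates around 0.02 Hz, graded mixed
selectivity to position, speed and motion direction, and 50-trial
forced-alternation T-maze sessions with a configurable correct-choice rate
(~71% in the emulated condition).

Events are drawn by per-frame Bernoulli thinning of an inhomogeneous Poisson
rate: p(event at frame t) = rate(state_t) * dt, clipped to [0, 1].  Tuning
modulation factors are normalized to unit mean over the session occupancy, so
a neuron's ``baseline_rate`` is its expected mean event rate regardless of
tuning strength.  Randomness flows from a single session seed; each neuron
draws from its own deterministic sub-stream so that neuron i's train does not
depend on how many other neurons are simulated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import i0

from dgpop.behavior import compute_kinematics
from dgpop.core import PopulationRecording, TMazeSession, Trajectory, TuningSpec

__all__ = [
    "MotionParams",
    "TMazeTiming",
    "simulate_of_trajectory",
    "make_tuning_spec",
    "make_concentrated_spec",
    "generate_events",
    "simulate_tmaze_session",
    "DEFAULT_ARENA",
]

logger = logging.getLogger(__name__)

DEFAULT_ARENA = (40.0, 40.0)  # cm; typical mouse open field (configurable)


@dataclass
class MotionParams:
    """Ornstein-Uhlenbeck speed + diffusing-heading motion model.

    speed_mean, speed_sigma, speed_relax
        OU process ds = relax*(mean - s)*dt + sigma*dW, reflected at 0; the
        defaults put substantial occupancy in all three speed classes
        ([0,1), [1,5), >5 cm/s).
    heading_sigma
        heading diffusion (rad/sqrt(s)); walls reflect both position and
        heading.
    """

    speed_mean: float = 4.0  # cm/s
    speed_sigma: float = 3.0  # cm/s per sqrt(s)
    speed_relax: float = 0.5  # 1/s
    heading_sigma: float = 1.5  # rad per sqrt(s)


@dataclass
class TMazeTiming:
    """Per-trial timing of the simulated forced-alternation task (seconds,
    relative to trial start).  The defaults leave room for the full 5-s
    forced-arm window after the forced turn and the full 6-to-1-s decision
    window before the free-choice turn."""

    trial_duration: float = 24.0
    forced_turn_time: float = 6.0
    free_choice_turn_time: float = 18.0
    arm_run_time: float = 3.0  # turn -> arm end


def simulate_of_trajectory(
    duration: float = 1800.0,
    frame_rate: float = 3.0,
    arena: tuple = DEFAULT_ARENA,
    motion_params: MotionParams = None,
    seed: int = 0,
) -> Trajectory:
    """Simulate a bounded smooth random walk in an open-field arena.

    Parameters
    ----------
    duration
        Session length in seconds (default 1800 s = 30 min).
    frame_rate
        Sampling rate in Hz (default 3 Hz).
    arena
        (width, height) in cm.
    motion_params
        :class:`MotionParams`; defaults produce realistic occupancy and
        speed coverage.
    seed
        Deterministic output for a given seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    w, h = arena
    if w <= 0 or h <= 0:
        raise ValueError("arena sides must be positive")
    mp = motion_params or MotionParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate
    sdt = np.sqrt(dt)

    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = w / 2.0, h / 2.0
    s = mp.speed_mean
    heading = rng.uniform(-np.pi, np.pi)
    for t in range(1, n):
        s += mp.speed_relax * (mp.speed_mean - s) * dt
        s += mp.speed_sigma * sdt * rng.standard_normal()
        s = abs(s)
        heading += mp.heading_sigma * sdt * rng.standard_normal()
        nx = x[t - 1] - s * dt * np.sin(heading)
        ny = y[t - 1] + s * dt * np.cos(heading)
        # reflecting walls: mirror position and heading
        if nx < 0 or nx > w:
            nx = -nx if nx < 0 else 2 * w - nx
            heading = -heading
        if ny < 0 or ny > h:
            ny = -ny if ny < 0 else 2 * h - ny
            heading = np.pi - heading
        x[t] = min(max(nx, 0.0), w)
        y[t] = min(max(ny, 0.0), h)
    times = np.arange(n) * dt
    return Trajectory(times, x, y, arena_width=w, arena_height=h)


_STRUCTURES = ("independent", "dependent", "exclusive")
_TYPES = ("place", "speed", "direction", "lr_arm", "lr_decision")

DEFAULT_GAIN_RANGES = {
    "place_gain_max": 6.0,
    "speed_slope_max": 0.15,  # per cm/s
    "direction_kappa_max": 2.0,
    "lr_gain_max": 0.9,
}


def make_tuning_spec(
    n_neurons: int = 70,
    structure: str = "independent",
    gain_ranges: dict = None,
    seed: int = 0,
    arena: tuple = DEFAULT_ARENA,
    baseline_rate: float = 0.02,
) -> TuningSpec:
    """Draw a population tuning specification under a coding-structure model.

    ``structure`` controls the joint distribution of per-type tuning
    strengths across neurons:

    independent
        strengths drawn independently per type (population correlation ~ 0);
    dependent
        strengths positively coupled through a shared per-neuron latent;
    exclusive
        each neuron strongly tuned to at most one type.

    Strengths u in [0, 1] scale the maxima in ``gain_ranges``
    (see :data:`DEFAULT_GAIN_RANGES`).
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if structure not in _STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; one of {_STRUCTURES}")
    gr = dict(DEFAULT_GAIN_RANGES)
    if gain_ranges:
        gr.update(gain_ranges)
    rng = np.random.default_rng(seed)
    n = n_neurons

    if structure == "independent":
        u = {t: rng.uniform(0, 1, n) for t in _TYPES}
    elif structure == "dependent":
        common = rng.uniform(0, 1, n)
        u = {
            t: np.clip(common + 0.15 * rng.standard_normal(n), 0, 1) for t in _TYPES
        }
    else:  # exclusive
        assigned = rng.integers(0, len(_TYPES), n)
        u = {}
        for k, t in enumerate(_TYPES):
            strong = rng.uniform(0.5, 1.0, n)
            weak = rng.uniform(0.0, 0.05, n)
            u[t] = np.where(assigned == k, strong, weak)

    w, h = arena
    return TuningSpec(
        baseline_rate=np.full(n, baseline_rate),
        place_center=np.column_stack(
            [rng.uniform(0, w, n), rng.uniform(0, h, n)]
        ),
        place_width=rng.uniform(4.0, 8.0, n),
        place_gain=u["place"] * gr["place_gain_max"],
        speed_slope=u["speed"] * gr["speed_slope_max"],
        direction_pref=rng.uniform(-np.pi, np.pi, n),
        direction_concentration=u["direction"] * gr["direction_kappa_max"],
        lr_arm_gain=u["lr_arm"] * gr["lr_gain_max"],
        lr_arm_pref=rng.choice([-1.0, 1.0], n),
        lr_decision_gain=u["lr_decision"] * gr["lr_gain_max"],
        lr_decision_pref=rng.choice([-1.0, 1.0], n),
        structure_label=structure,
    )


def make_concentrated_spec(
    n_neurons: int = 70,
    frac_tuned: float = 0.3,
    seed: int = 0,
    arena: tuple = DEFAULT_ARENA,
    baseline_rate: float = 0.3,
    place_gain: float = 25.0,
    speed_slope: float = 0.35,
    place_width_range: tuple = (8.0, 12.0),
    gain_scale: float = 1.0,
) -> TuningSpec:
    """Spec with spatial and speed tuning concentrated in disjoint subsets.

    A fraction ``frac_tuned`` of neurons carries strong place tuning, a
    disjoint equal fraction strong speed tuning, and the remainder is
    untuned — the configuration used to probe whether the deletion analysis
    separates information types carried by different subpopulations.  Rates
    and gains are elevated relative to the in-vivo-scale defaults so
    per-neuron information is estimable in short sessions; place fields are
    wide enough (8-12 cm) that a handful of cells tiles the arena.
    ``gain_scale`` scales both tuning strengths, modelling between-animal
    differences in tuning quality.
    """
    rng = np.random.default_rng(seed)
    n = n_neurons
    k = int(round(frac_tuned * n))
    perm = rng.permutation(n)
    place_idx, speed_idx = perm[:k], perm[k : 2 * k]
    pg = np.zeros(n)
    pg[place_idx] = place_gain * gain_scale * rng.uniform(0.7, 1.3, k)
    ss = np.zeros(n)
    ss[speed_idx] = speed_slope * gain_scale * rng.uniform(0.7, 1.3, k)
    w, h = arena
    return TuningSpec(
        baseline_rate=np.full(n, baseline_rate),
        place_center=np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)]),
        place_width=rng.uniform(*place_width_range, n),
        place_gain=pg,
        speed_slope=ss,
        direction_pref=rng.uniform(-np.pi, np.pi, n),
        direction_concentration=np.zeros(n),
        structure_label="independent",
    )


def _rate_series(trajectory: Trajectory, spec: TuningSpec, normalize: bool) -> np.ndarray:
    """Per-frame event rate (events/s) for every neuron, (n_frames, n)."""
    kin = compute_kinematics(trajectory)
    n_frames = trajectory.n_frames
    n = spec.n_neurons
    rates = np.empty((n_frames, n))
    dx = trajectory.x[:, None] - np.asarray(spec.place_center)[:, 0][None, :]
    dy = trajectory.y[:, None] - np.asarray(spec.place_center)[:, 1][None, :]
    width = np.asarray(spec.place_width)[None, :]
    place = 1.0 + np.asarray(spec.place_gain)[None, :] * np.exp(
        -(dx**2 + dy**2) / (2.0 * width**2)
    )
    mean_speed = float(np.mean(kin.speed))
    speed = np.maximum(
        0.0,
        1.0
        + np.asarray(spec.speed_slope)[None, :]
        * (kin.speed[:, None] - mean_speed),
    )
    kappa = np.asarray(spec.direction_concentration)[None, :]
    ang = kin.direction[:, None] - np.asarray(spec.direction_pref)[None, :]
    with np.errstate(invalid="ignore"):
        vm = np.exp(kappa * np.cos(ang)) / i0(kappa)
    vm[~kin.valid, :] = 1.0  # direction undefined -> no directional modulation
    mod = place * speed * vm
    if normalize:
        mod /= np.mean(mod, axis=0, keepdims=True)
    rates[:] = np.asarray(spec.baseline_rate)[None, :] * mod
    return rates


def generate_events(
    trajectory: Trajectory,
    spec: TuningSpec,
    seed: int = 0,
    normalize_mean: bool = True,
) -> PopulationRecording:
    """Draw binarized event trains from an inhomogeneous Poisson model.

    Per frame, p(event) = rate * dt clipped to [0, 1] (clipping is logged as
    a warning if it occurs).  With ``normalize_mean`` (default) each neuron's
    modulation is scaled to unit occupancy mean so its realized mean rate
    matches ``spec.baseline_rate``.
    """
    if trajectory.n_frames == 0 or spec.n_neurons == 0:
        raise ValueError("trajectory and spec must be nonempty")
    rates = _rate_series(trajectory, spec, normalize=normalize_mean)
    dt = trajectory.dt
    p = rates * dt
    n_over = int(np.count_nonzero(p > 1.0))
    if n_over:
        warnings.warn(
            f"{n_over} frame-neuron rate values exceed 1/dt; clipping p to 1",
            RuntimeWarning,
        )
        logger.warning("clipped %d event probabilities to 1", n_over)
    np.clip(p, 0.0, 1.0, out=p)
    children = np.random.SeedSequence(seed).spawn(spec.n_neurons)
    events = np.empty((trajectory.n_frames, spec.n_neurons), dtype=np.uint8)
    for j in range(spec.n_neurons):
        rng = np.random.default_rng(children[j])
        events[:, j] = rng.random(trajectory.n_frames) < p[:, j]
    ids = [f"n{j:03d}" for j in range(spec.n_neurons)]
    return PopulationRecording(events, ids, trajectory.frame_rate)


# ---------------------------------------------------------------------------
# T-maze


def _maze_waypoints(timing: TMazeTiming, forced: str, choice: str):
    """Waypoint (t, x, y) list for one trial on a schematic T-maze.

    Stem runs south->north from (20, 0) to the junction (20, 40); the left
    (west) arm ends at (0, 40) and the right (east) arm at (40, 40); stem
    40 cm, arms 20 cm (configurable only through the arena mapping here).
    """
    start = (20.0, 0.0)
    junction = (20.0, 40.0)
    arm_end = {"L": (0.0, 40.0), "R": (40.0, 40.0)}
    tf = timing.forced_turn_time
    tc = timing.free_choice_turn_time
    run = timing.arm_run_time
    # dwell at forced arm end, return to start, re-approach the junction
    return_done = tf + run + (tc - (tf + run)) * 0.6
    return [
        (0.0, *start),
        (tf, *junction),
        (tf + run, *arm_end[forced]),
        (return_done, *start),
        (tc, *junction),
        (tc + run, *arm_end[choice]),
        (timing.trial_duration, *arm_end[choice]),
    ]


def simulate_tmaze_session(
    n_trials: int = 50,
    correct_rate: float = 0.714,
    timing_params: TMazeTiming = None,
    spec: TuningSpec = None,
    seed: int = 0,
    frame_rate: float = 3.0,
    arm_window_s: float = 5.0,
    decision_window: tuple = (6.0, 1.0),
) -> TMazeSession:
    """Simulate a forced-alternation T-maze session with aligned recording.

    Each trial is a forced-choice run (random side) followed by a free-choice
    run; the trial is correct iff the free choice is opposite the forced
    side, and free choices are drawn so the expected correct fraction equals
    ``correct_rate`` (default 0.714, the emulated wild-type performance).
    Neurons with nonzero ``lr_arm_gain`` / ``lr_decision_gain`` in ``spec``
    fire differentially by side within the forced-arm window (first
    ``arm_window_s`` s after the forced turn) and the decision window
    (``decision_window`` = (a, b): from a to b seconds before the free-choice
    turn), respectively.
    """
    if not 0.0 <= correct_rate <= 1.0:
        raise ValueError("correct_rate must be in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    timing = timing_params or TMazeTiming()
    if timing.forced_turn_time + arm_window_s > timing.free_choice_turn_time:
        raise ValueError("forced-arm window does not fit before the free-choice turn")
    if timing.free_choice_turn_time - decision_window[0] < timing.forced_turn_time:
        raise ValueError("decision window extends before the forced turn")
    if timing.free_choice_turn_time + timing.arm_run_time > timing.trial_duration:
        raise ValueError("free-choice run does not fit in the trial duration")
    if spec is None:
        spec = make_tuning_spec(seed=seed)

    rng = np.random.default_rng(seed)
    forced = rng.choice(["L", "R"], n_trials)
    correct = rng.random(n_trials) < correct_rate
    opposite = np.where(forced == "L", "R", "L")
    free = np.where(correct, opposite, forced)

    dt = 1.0 / frame_rate
    frames_per_trial = int(round(timing.trial_duration * frame_rate))
    n_frames = frames_per_trial * n_trials
    times = np.arange(n_frames) * dt
    x = np.empty(n_frames)
    y = np.empty(n_frames)
    rows = []
    for k in range(n_trials):
        t0 = k * timing.trial_duration
        wp = _maze_waypoints(timing, forced[k], free[k])
        wt = np.array([p[0] for p in wp])
        wx = np.array([p[1] for p in wp])
        wy = np.array([p[2] for p in wp])
        sl = slice(k * frames_per_trial, (k + 1) * frames_per_trial)
        rel = times[sl] - t0
        x[sl] = np.interp(rel, wt, wx)
        y[sl] = np.interp(rel, wt, wy)
        rows.append(
            {
                "trial_id": k,
                "forced_side": forced[k],
                "free_choice": free[k],
                "correct": bool(correct[k]),
                "forced_turn_time_s": t0 + timing.forced_turn_time,
                "free_choice_turn_time_s": t0 + timing.free_choice_turn_time,
            }
        )
    trials = pd.DataFrame(rows)
    trajectory = Trajectory(times, x, y, arena_width=40.0, arena_height=40.0)

    # per-frame side modulation factors
    n = spec.n_neurons
    factor = np.ones((n_frames, n))
    side_sign = {"L": 1.0, "R": -1.0}
    arm_pref = np.asarray(spec.lr_arm_pref)
    arm_gain = np.asarray(spec.lr_arm_gain)
    dec_pref = np.asarray(spec.lr_decision_pref)
    dec_gain = np.asarray(spec.lr_decision_gain)
    for k in range(n_trials):
        tf = trials.loc[k, "forced_turn_time_s"]
        tc = trials.loc[k, "free_choice_turn_time_s"]
        a0 = int(round(tf * frame_rate))
        a1 = a0 + int(round(arm_window_s * frame_rate))
        s = side_sign[forced[k]]
        factor[a0:a1] *= np.maximum(0.0, 1.0 + arm_gain * arm_pref * s)[None, :]
        d0 = int(round((tc - decision_window[0]) * frame_rate))
        d1 = int(round((tc - decision_window[1]) * frame_rate))
        s = side_sign[free[k]]
        factor[d0:d1] *= np.maximum(0.0, 1.0 + dec_gain * dec_pref * s)[None, :]

    p = np.clip(np.asarray(spec.baseline_rate)[None, :] * factor * dt, 0.0, 1.0)
    children = np.random.SeedSequence(seed).spawn(n + 1)
    events = np.empty((n_frames, n), dtype=np.uint8)
    for j in range(n):
        sub = np.random.default_rng(children[j + 1])
        events[:, j] = sub.random(n_frames) < p[:, j]
    ids = [f"n{j:03d}" for j in range(n)]
    recording = PopulationRecording(events, ids, frame_rate)
    return TMazeSession(trials=trials, trajectory=trajectory, recording=recording)
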
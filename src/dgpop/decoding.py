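"""Population decoding with shuffled-data chance levels.

Continuous behavioral variables (position, speed, motion direction) are
regressed frame-by-frame from a sliding window of population event vectors;
direction is regressed as its (sin, cos) embedding and recomposed with atan2
to avoid the 2-pi discontinuity.  Cross-validation uses contiguous temporal
folds so that autocorrelated frames never straddle the train/test boundary.
T-maze left/right (current arm or future choice) is decoded per trial from
window count vectors with leave-one-trial-out cross-validation.

Chance levels follow the shuffled-data convention: the identical decoder is
retrained on data whose event trains were independently circularly shifted
per neuron (open field) or whose trial side labels were permuted (T-maze),
and evaluated against the true held-out targets.

Models: ``linear`` (ridge regression / logistic classification; the default
for analyses and tests) and ``feedforward`` (one-hidden-layer MLP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.neural_network import MLPClassifier, MLPRegressor

from dgpop.behavior import compute_kinematics
from dgpop.core import PopulationRecording, Trajectory
from dgpop.lr import PeriodActivity

__all__ = [
    "DecodingResult",
    "train_and_decode",
    "evaluate",
    "chance_level",
    "decode_lr",
    "chance_level_lr",
    "circular_abs_error",
]

TARGETS = ("position", "speed", "direction")
METRIC_NAMES = {
    "position": "mean_absolute_error_cm",
    "speed": "pearson_r",
    "direction": "mean_absolute_circular_error_rad",
    "lr": "accuracy_percent",
}

DEFAULT_HYPERPARAMS = {
    "alpha": 10.0,  # ridge penalty
    "hidden_units": 64,
    "max_iter": 200,
    "C": 1.0,  # logistic regression inverse penalty
}


@dataclass
class DecodingResult:
    """Out-of-fold predictions and the evaluation metric for one target."""

    target_name: str
    predictions: np.ndarray
    observations: np.ndarray
    metric_name: str
    metric_value: float = np.nan
    chance_value: float = np.nan
    model_name: str = "linear"
    cv_spec: str = ""
    valid_mask: np.ndarray = None


def _window_features(events: np.ndarray, window: int) -> np.ndarray:
    """Flattened sliding window of population vectors ending at each frame.

    Frames earlier than the window are zero-padded.
    """
    n, d = events.shape
    X = np.zeros((n, d * window))
    ev = events.astype(float)
    for k in range(window):
        X[k:, k * d : (k + 1) * d] = ev[: n - k]
    return X


def _contiguous_folds(n: int, k: int):
    edges = np.linspace(0, n, k + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(k)]


def _make_regressor(model: str, hp: dict, seed: int):
    if model == "linear":
        return Ridge(alpha=hp["alpha"])
    if model == "feedforward":
        return MLPRegressor(
            hidden_layer_sizes=(hp["hidden_units"],),
            max_iter=hp["max_iter"],
            random_state=seed,
        )
    if model == "recurrent":
        raise NotImplementedError(
            "no recurrent sequence decoder is provided; use 'linear' or 'feedforward'"
        )
    raise ValueError(f"unknown model {model!r}")


def _targets_from_trajectory(trajectory: Trajectory, target: str):
    kin = compute_kinematics(trajectory)
    if target == "position":
        return np.column_stack([trajectory.x, trajectory.y]), np.ones(
            trajectory.n_frames, bool
        )
    if target == "speed":
        return kin.speed[:, None], np.ones(trajectory.n_frames, bool)
    if target == "direction":
        ang = np.where(kin.valid, kin.direction, 0.0)
        return np.column_stack([np.sin(ang), np.cos(ang)]), kin.valid
    raise ValueError(f"unknown target {target!r}; one of {TARGETS}")


def train_and_decode(
    recording: PopulationRecording,
    trajectory: Trajectory,
    target: str = "position",
    model: str = "linear",
    n_folds: int = 5,
    window: int = 10,
    hyperparams: dict = None,
    seed: int = 0,
    _train_events: np.ndarray = None,
) -> DecodingResult:
    """Decode a behavioral variable out-of-fold from population activity.

    Parameters
    ----------
    recording, trajectory
        Frame-aligned event matrix and position track.
    target
        'position' (x, y in cm), 'speed' (cm/s) or 'direction' (rad,
        decoded via sin/cos embedding).
    model
        'linear' (ridge, deterministic) or 'feedforward' (MLP, seeded).
    n_folds
        Contiguous temporal cross-validation folds (>= 2).
    window
        Input window length in frames ending at the decoded frame.
    _train_events
        Internal hook for chance-level computation: an alternative event
        matrix used for *training* only (e.g. circularly shifted data);
        evaluation frames keep their true targets.
    """
    if recording.n_neurons < 1:
        raise ValueError("need at least one neuron")
    if n_folds < 2:
        raise ValueError("need at least 2 cross-validation folds")
    if recording.n_frames != trajectory.n_frames:
        raise ValueError("recording/trajectory frame count mismatch")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    Y, valid = _targets_from_trajectory(trajectory, target)
    X_test = _window_features(recording.events, window)
    if not np.all(np.isfinite(X_test)):
        raise ValueError("non-finite features")
    X_train_src = (
        X_test
        if _train_events is None
        else _window_features(_train_events, window)
    )
    n = recording.n_frames
    preds = np.empty_like(Y, dtype=float)
    for i, (lo, hi) in enumerate(_contiguous_folds(n, n_folds)):
        train_idx = np.r_[0:lo, hi:n]
        reg = _make_regressor(model, hp, seed + i)
        reg.fit(X_train_src[train_idx], Y[train_idx])
        out = reg.predict(X_test[lo:hi])
        preds[lo:hi] = out.reshape(hi - lo, -1)
    if target == "direction":
        obs = np.arctan2(Y[:, 0], Y[:, 1])
        pred = np.arctan2(preds[:, 0], preds[:, 1])
    elif target == "speed":
        obs, pred = Y[:, 0], preds[:, 0]
    else:
        obs, pred = Y, preds
    result = DecodingResult(
        target_name=target,
        predictions=pred,
        observations=obs,
        metric_name=METRIC_NAMES[target],
        model_name=model,
        cv_spec=f"{n_folds} contiguous temporal folds",
        valid_mask=valid,
    )
    result.metric_value = evaluate(result)
    return result


def circular_abs_error(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute angular difference wrapped to [0, pi]."""
    d = np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))
    return np.abs(d)


def evaluate(result: DecodingResult) -> float:
    """Compute the target's headline metric from out-of-fold predictions.

    position: mean absolute Euclidean error (cm); speed: Pearson correlation
    between observed and decoded series; direction: mean absolute circular
    error (rad, in [0, pi]); lr: percent of trials classified correctly.
    """
    pred, obs = result.predictions, result.observations
    if len(np.atleast_1d(pred)) == 0:
        raise ValueError("empty predictions")
    mask = (
        result.valid_mask
        if result.valid_mask is not None
        else np.ones(len(np.atleast_1d(obs)), bool)
    )
    if result.target_name == "position":
        err = np.linalg.norm(pred[mask] - obs[mask], axis=1)
        return float(np.mean(err))
    if result.target_name == "speed":
        o = obs[mask]
        if np.std(o) == 0:
            return np.nan  # correlation undefined for constant speed
        return float(pearsonr(o, pred[mask])[0])
    if result.target_name == "direction":
        return float(np.mean(circular_abs_error(pred[mask], obs[mask])))
    if result.target_name == "lr":
        return float(np.mean(pred[mask] == obs[mask]) * 100.0)
    raise ValueError(f"unknown target {result.target_name!r}")


def chance_level(
    recording: PopulationRecording,
    trajectory: Trajectory,
    target: str = "position",
    model: str = "linear",
    n_folds: int = 5,
    window: int = 10,
    n_reps: int = 10,
    min_shift_s: float = 20.0,
    hyperparams: dict = None,
    seed: int = 0,
) -> np.ndarray:
    """Shuffled-data chance distribution of the decoding metric.

    Each repetition circularly shifts every neuron's event train by an
    independent random offset (>= ``min_shift_s``), retrains the decoder on
    the shifted data and evaluates its predictions against the *true*
    held-out targets.  Returns the metric per repetition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = recording.n_frames
    lo = int(np.ceil(min_shift_s * recording.frame_rate))
    vals = np.empty(n_reps)
    for r in range(n_reps):
        shifts = rng.integers(lo, n - lo + 1, size=recording.n_neurons)
        shuffled = np.empty_like(recording.events)
        for j, s in enumerate(shifts):
            shuffled[:, j] = np.roll(recording.events[:, j], s)
        res = train_and_decode(
            recording,
            trajectory,
            target=target,
            model=model,
            n_folds=n_folds,
            window=window,
            hyperparams=hyperparams,
            seed=seed + 1000 + r,
            _train_events=shuffled,
        )
        vals[r] = res.metric_value
    return vals


def _make_classifier(model: str, hp: dict, seed: int):
    if model == "linear":
        return LogisticRegression(C=hp["C"], max_iter=1000)
    if model == "feedforward":
        return MLPClassifier(
            hidden_layer_sizes=(hp["hidden_units"],),
            max_iter=hp["max_iter"],
            random_state=seed,
        )
    if model == "recurrent":
        raise NotImplementedError(
            "no recurrent sequence decoder is provided; use 'linear' or 'feedforward'"
        )
    raise ValueError(f"unknown model {model!r}")


def decode_lr(
    activity: PeriodActivity,
    model: str = "linear",
    hyperparams: dict = None,
    seed: int = 0,
    _train_sides: np.ndarray = None,
) -> DecodingResult:
    """Binary left/right decoding from period count vectors, leave-one-trial-out.

    Returns per-trial out-of-fold side predictions and accuracy (%).
    """
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    X = activity.counts
    y = activity.sides if _train_sides is None else np.asarray(_train_sides)
    n = activity.n_trials
    if n < 3:
        raise ValueError("need at least 3 trials for leave-one-trial-out")
    preds = np.empty(n, dtype=object)
    for i in range(n):
        train = np.r_[0:i, i + 1 : n]
        if len(np.unique(y[train])) < 2:
            preds[i] = y[train][0]
            continue
        clf = _make_classifier(model, hp, seed)
        clf.fit(X[train], y[train])
        preds[i] = clf.predict(X[i : i + 1])[0]
    result = DecodingResult(
        target_name="lr",
        predictions=np.array([str(p) for p in preds]),
        observations=np.asarray(activity.sides),
        metric_name=METRIC_NAMES["lr"],
        model_name=model,
        cv_spec="leave-one-trial-out",
    )
    result.metric_value = evaluate(result)
    return result


def chance_level_lr(
    activity: PeriodActivity,
    model: str = "linear",
    n_reps: int = 10,
    hyperparams: dict = None,
    seed: int = 0,
) -> np.ndarray:
    """Chance LR-decoding accuracy: train on permuted side labels, evaluate
    against the true held-out labels."""
    rng = np.random.default_rng(seed)
    vals = np.empty(n_reps)
    for r in range(n_reps):
        perm_sides = np.asarray(activity.sides)[rng.permutation(activity.n_trials)]
        res = decode_lr(
            activity,
            model=model,
            hyperparams=hyperparams,
            seed=seed + r,
            _train_sides=perm_sides,
        )
        vals[r] = res.metric_value
    return vals
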
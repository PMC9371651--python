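"""Left/right selectivity in the forced-alternation T-maze.

Two trial-locked windows are analysed: the *forced-arm period* (the 5 s after
the forced turn; side label = the arm the animal is in) and the *decision
period* (6 to 1 s before the free-choice turn; side label = the side the
animal will choose, i.e. its future location).  For each neuron the LR index

    LR = (r_L - r_R) / (r_L + r_R)

compares its mean event rate on left- and right-labeled trials; it lies in
[-1, 1] and grows in magnitude with differential activity.  Significance is
assessed against a trial-label permutation null (side labels shuffled across
trials, preserving the L/R counts), the appropriate exchangeable null for
trial-structured data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from dgpop.core import TMazeSession
from dgpop.information import cohens_d  # shared effect-size definition

__all__ = [
    "PeriodActivity",
    "LRIndexResult",
    "extract_period_activity",
    "lr_index",
    "lr_shuffle_null",
    "lr_index_with_null",
    "population_lr_test",
]

PERIODS = ("forced_arm", "decision")
FORCED_ARM_WINDOW_S = 5.0  # [turn, turn + 5 s)
DECISION_WINDOW = (6.0, 1.0)  # [turn - 6 s, turn - 1 s)


@dataclass
class PeriodActivity:
    """Per-trial, per-neuron event counts within one analysis window."""

    counts: np.ndarray  # (n_trials, n_neurons)
    sides: np.ndarray  # 'L'/'R' label per trial
    trial_ids: np.ndarray
    period: str
    window_s: float
    frames_per_window: int

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]


@dataclass
class LRIndexResult:
    """One neuron's LR index with optional trial-shuffle null."""

    lr_index: float
    rate_l: float  # events/s on L-labeled trials
    rate_r: float
    inactive: bool  # no events on either side
    null: np.ndarray = None
    null_p95_abs: float = np.nan
    exceeds_p95_abs: bool = False


def extract_period_activity(session: TMazeSession, period: str) -> PeriodActivity:
    """Event counts per trial and neuron in the forced-arm or decision window.

    Forced-arm: the 5-s window after the forced turn, labeled by the current
    arm (the forced side).  Decision: the window 6 to 1 s before the
    free-choice turn, labeled by the *future* chosen side.  Trials whose
    window does not fit within the session are excluded with a warning.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; one of {PERIODS}")
    if session.recording is None:
        raise ValueError("session has no aligned recording")
    rate = session.frame_rate
    events = session.recording.events
    n_frames = events.shape[0]
    counts, sides, ids = [], [], []
    for _, tr in session.trials.iterrows():
        if period == "forced_arm":
            t0 = tr["forced_turn_time_s"]
            t1 = t0 + FORCED_ARM_WINDOW_S
            side = tr["forced_side"]
        else:
            turn = tr["free_choice_turn_time_s"]
            t0 = turn - DECISION_WINDOW[0]
            t1 = turn - DECISION_WINDOW[1]
            side = tr["free_choice"]
        f0 = int(round(t0 * rate))
        f1 = int(round(t1 * rate))
        if f0 < 0 or f1 > n_frames:
            warnings.warn(
                f"trial {tr['trial_id']}: {period} window outside session; excluded",
                RuntimeWarning,
            )
            continue
        counts.append(events[f0:f1].sum(axis=0))
        sides.append(side)
        ids.append(tr["trial_id"])
    if not counts:
        raise ValueError(f"no trial admits a full {period} window")
    frames = int(round((t1 - t0) * rate))
    return PeriodActivity(
        counts=np.array(counts, dtype=float),
        sides=np.array(sides),
        trial_ids=np.array(ids),
        period=period,
        window_s=t1 - t0,
        frames_per_window=frames,
    )


def _index_from_counts(counts, sides, window_s):
    is_l = sides == "L"
    n_l, n_r = int(is_l.sum()), int((~is_l).sum())
    if n_l == 0 or n_r == 0:
        raise ValueError("need at least one trial on each side")
    r_l = counts[is_l].sum() / (n_l * window_s)
    r_r = counts[~is_l].sum() / (n_r * window_s)
    if r_l + r_r == 0:
        return 0.0, r_l, r_r, True
    return (r_l - r_r) / (r_l + r_r), r_l, r_r, False


def lr_index(activity: PeriodActivity, neuron: int) -> LRIndexResult:
    """LR index (r_L - r_R)/(r_L + r_R) for one neuron.

    Rates are total events over total window time per side.  A neuron with no
    events on either side gets index 0 with the ``inactive`` flag set.
    """
    idx, r_l, r_r, inactive = _index_from_counts(
        activity.counts[:, neuron], activity.sides, activity.window_s
    )
    return LRIndexResult(
        lr_index=float(idx), rate_l=float(r_l), rate_r=float(r_r), inactive=inactive
    )


def lr_shuffle_null(
    activity: PeriodActivity,
    neuron: int,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Trial-label permutation null of the LR index for one neuron.

    Each shuffle permutes the side labels across trials (L/R counts
    preserved) and recomputes the index.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    counts = activity.counts[:, neuron]
    sides = activity.sides
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(len(sides))
        null[s] = _index_from_counts(counts, sides[perm], activity.window_s)[0]
    return null


def lr_index_with_null(
    activity: PeriodActivity,
    neuron: int,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> LRIndexResult:
    """LR index plus its |null| 95th-percentile threshold."""
    res = lr_index(activity, neuron)
    null = lr_shuffle_null(activity, neuron, n_shuffles, seed)
    res.null = null
    res.null_p95_abs = float(np.percentile(np.abs(null), 95))
    res.exceeds_p95_abs = bool(abs(res.lr_index) > res.null_p95_abs)
    return res


def population_lr_test(results: list, n_replicates: int = 1000, seed: int = 0):
    """Permutation test of the population mean |LR index| against the nulls.

    Mirrors the population information test: replicates draw one |null| value
    per neuron; Cohen's d compares observed |index| values with per-neuron
    mean |null| values (pooled SD).
    """
    from dgpop.information import PopulationInfoTest

    usable = [r for r in results if r.null is not None and not r.inactive]
    if len(usable) < 2:
        raise ValueError("need at least 2 active neurons with nulls")
    obs = np.array([abs(r.lr_index) for r in usable])
    nulls = [np.abs(r.null) for r in usable]
    null_means = np.array([nl.mean() for nl in nulls])
    rng = np.random.default_rng(seed)
    draws = np.column_stack(
        [nl[rng.integers(0, len(nl), size=n_replicates)] for nl in nulls]
    )
    rep_means = draws.mean(axis=1)
    obs_mean = obs.mean()
    p = (1.0 + np.sum(rep_means >= obs_mean)) / (n_replicates + 1.0)
    n_thresh = sum(1 for r in usable if np.isfinite(r.null_p95_abs))
    frac = (
        100.0 * sum(bool(r.exceeds_p95_abs) for r in usable) / n_thresh
        if n_thresh
        else np.nan
    )
    return PopulationInfoTest(
        p_value=float(p),
        cohens_d=float(cohens_d(obs, null_means)),
        frac_above_p95=float(frac),
        n_neurons=len(usable),
        observed_mean=float(obs_mean),
        null_mean=float(null_means.mean()),
    )
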
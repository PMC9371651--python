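"""Skaggs information content with circular-shift shuffle nulls.

For a neuron with mean event rate lambda and per-state-bin rates lambda_i
occupied with probability p_i, the information carried per event is

    I = sum_i p_i * (lambda_i / lambda) * log2(lambda_i / lambda)

in bits per calcium transient (the per-spike form of the Skaggs spatial
information, applied to any discrete behavioral variable: position bins,
speed classes or direction arcs).  Significance per neuron is assessed
against a null distribution built by circularly shifting the event train
relative to behavior (default 1000 shuffles, minimum shift 20 s), which
preserves the train's within-train temporal statistics while destroying its
relation to behavior.  At the population level, a permutation test compares
the observed mean information with means of per-neuron null draws, with
Cohen's d as the effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InfoResult",
    "PopulationInfoTest",
    "information_content",
    "shuffle_null",
    "info_with_null",
    "population_info_test",
    "DEFAULT_MIN_OCCUPANCY_S",
]

DEFAULT_MIN_OCCUPANCY_S = 1.0  # bins visited less than this are excluded


@dataclass
class InfoResult:
    """One neuron's information content and its shuffle null."""

    info: float  # bits/transient (NaN if the neuron fired no events)
    p_occ: np.ndarray  # occupancy probability per included bin
    rates: np.ndarray  # events/s per included bin
    mean_rate: float
    n_events: int
    null: np.ndarray = None
    null_p95: float = np.nan
    exceeds_p95: bool = False
    percentile: float = np.nan

    @property
    def defined(self) -> bool:
        return np.isfinite(self.info)


@dataclass
class PopulationInfoTest:
    """Population-level permutation test of mean information vs null."""

    p_value: float
    cohens_d: float
    frac_above_p95: float  # percent of neurons exceeding their null p95
    n_neurons: int
    observed_mean: float
    null_mean: float


def _prepare_bins(state_labels, dt, min_occupancy_s):
    labels = np.asarray(state_labels)
    valid = labels >= 0
    counts = np.bincount(labels[valid])
    occ_s = counts * dt
    included = occ_s >= min_occupancy_s
    return labels, valid, included, occ_s


def _info_from_counts(event_counts, occ_s, included):
    """Skaggs information from per-bin event counts and occupancy (s)."""
    occ = occ_s[included]
    cnt = event_counts[..., included]
    total = cnt.sum(axis=-1)
    p = occ / occ.sum()
    rates = cnt / occ
    mean_rate = (p * rates).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = rates / np.expand_dims(mean_rate, -1)
        terms = np.where(cnt > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    info = terms.sum(axis=-1)
    return np.where(total > 0, info, np.nan), p, rates, mean_rate


def information_content(
    events: np.ndarray,
    state_labels: np.ndarray,
    dt: float,
    min_occupancy_s: float = DEFAULT_MIN_OCCUPANCY_S,
) -> InfoResult:
    """Information content (bits/transient) of one neuron for one variable.

    Parameters
    ----------
    events
        Binary event train.
    state_labels
        Integer state bin per frame; negative labels mark invalid frames
        (excluded together with their events).
    dt
        Frame duration in seconds.
    min_occupancy_s
        Bins occupied for less than this are excluded and occupancy
        probabilities renormalized (rate estimates there are unstable).

    Returns an :class:`InfoResult` with ``info`` NaN (undefined) when the
    neuron fired no events in the included bins.
    """
    events = np.asarray(events)
    labels, valid, included, occ_s = _prepare_bins(state_labels, dt, min_occupancy_s)
    if len(events) != len(labels):
        raise ValueError("events/state length mismatch")
    if included.sum() < 2:
        raise ValueError("need at least 2 included state bins")
    counts = np.bincount(labels[valid], weights=events[valid], minlength=len(occ_s))
    info, p, rates, mean_rate = _info_from_counts(counts, occ_s, included)
    return InfoResult(
        info=float(info),
        p_occ=p,
        rates=rates,
        mean_rate=float(mean_rate),
        n_events=int(counts[included].sum()),
    )


def shuffle_null(
    events: np.ndarray,
    state_labels: np.ndarray,
    dt: float,
    n_shuffles: int = 1000,
    min_shift_s: float = 20.0,
    seed: int = 0,
    min_occupancy_s: float = DEFAULT_MIN_OCCUPANCY_S,
) -> np.ndarray:
    """Null information distribution from circular shifts of the event train.

    Each shuffle shifts the train relative to behavior by a uniform offset in
    [min_shift_s, T - min_shift_s] (wrapping around), preserving the event
    count, and recomputes the information content.
    """
    events = np.asarray(events)
    labels, valid, included, occ_s = _prepare_bins(state_labels, dt, min_occupancy_s)
    n = len(events)
    T = n * dt
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if T < 2 * min_shift_s:
        raise ValueError("session shorter than twice the minimum shift")
    rng = np.random.default_rng(seed)
    lo = int(np.ceil(min_shift_s / dt))
    hi = n - lo
    shifts = rng.integers(lo, hi + 1, size=n_shuffles)
    ev_idx = np.flatnonzero(events)
    n_bins = len(occ_s)
    null = np.empty(n_shuffles)
    if ev_idx.size == 0:
        null[:] = np.nan
        return null
    # shifting events by +s aligns event at t with behavior at t+s
    shifted = (ev_idx[None, :] + shifts[:, None]) % n
    lab = labels[shifted]  # (n_shuffles, n_events)
    ok = lab >= 0
    counts = np.zeros((n_shuffles, n_bins))
    rows = np.repeat(np.arange(n_shuffles), ok.sum(axis=1))
    np.add.at(counts, (rows, lab[ok]), 1.0)
    info, _, _, _ = _info_from_counts(counts, occ_s, included)
    return info


def info_with_null(
    events: np.ndarray,
    state_labels: np.ndarray,
    dt: float,
    n_shuffles: int = 1000,
    min_shift_s: float = 20.0,
    seed: int = 0,
    min_occupancy_s: float = DEFAULT_MIN_OCCUPANCY_S,
) -> InfoResult:
    """Observed information plus its shuffle null, threshold and percentile."""
    res = information_content(events, state_labels, dt, min_occupancy_s)
    null = shuffle_null(
        events, state_labels, dt, n_shuffles, min_shift_s, seed, min_occupancy_s
    )
    res.null = null
    finite_null = null[np.isfinite(null)]
    if finite_null.size:
        res.null_p95 = float(np.percentile(finite_null, 95))
        if res.defined:
            res.exceeds_p95 = bool(res.info > res.null_p95)
            res.percentile = float(np.mean(finite_null <= res.info) * 100.0)
    return res


def population_info_test(
    info_results: list,
    n_replicates: int = 1000,
    seed: int = 0,
) -> PopulationInfoTest:
    """Permutation test of population-mean information against the nulls.

    Each replicate draws one null value per neuron and averages them; the
    p-value is the (+1-smoothed) fraction of replicate means at least as
    large as the observed mean, floored at 1/(n_replicates+1).  Cohen's d is
    the standardized difference between the observed values and the
    per-neuron null means (pooled SD).
    """
    usable = [
        r
        for r in info_results
        if r.defined and r.null is not None and np.isfinite(r.null).any()
    ]
    if len(usable) < 2:
        raise ValueError("need at least 2 neurons with defined information")
    obs = np.array([r.info for r in usable])
    nulls = [r.null[np.isfinite(r.null)] for r in usable]
    null_means = np.array([nl.mean() for nl in nulls])
    rng = np.random.default_rng(seed)
    rep_means = np.empty(n_replicates)
    draws = np.column_stack(
        [nl[rng.integers(0, len(nl), size=n_replicates)] for nl in nulls]
    )
    rep_means = draws.mean(axis=1)
    obs_mean = obs.mean()
    p = (1.0 + np.sum(rep_means >= obs_mean)) / (n_replicates + 1.0)
    d = cohens_d(obs, null_means)
    n_thresh = sum(1 for r in usable if np.isfinite(r.null_p95))
    frac = (
        100.0 * sum(bool(r.exceeds_p95) for r in usable) / n_thresh
        if n_thresh
        else np.nan
    )
    return PopulationInfoTest(
        p_value=float(p),
        cohens_d=float(d),
        frac_above_p95=float(frac),
        n_neurons=len(usable),
        observed_mean=float(obs_mean),
        null_mean=float(null_means.mean()),
    )


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled standard deviation (unpaired)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    var_a = a.var(ddof=1) if na > 1 else 0.0
    var_b = b.var(ddof=1) if nb > 1 else 0.0
    pooled = np.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2))
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return (a.mean() - b.mean()) / pooled
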
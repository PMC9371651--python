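"""Ordered-neuron-deletion curves and the independence (effect-size) analysis.

Neurons are deleted from each animal's dataset one group at a time under a
named order (by decreasing or increasing per-neuron score — information
content or |LR index| — or at random), the decoder is retrained from scratch
on the survivors at each retention level (100% down to 10% in steps of 10),
and performance is measured out-of-fold.  Two deletion orders are compared by
Cohen's d across animals at the nine levels 90..10%, summarized by the mean
|d|; the orders x orders matrix of mean |d| exposes which information types
are carried by the same or by disjoint subpopulations (a large random-vs-
descending |d| for the scored type, a small one across types, indicates
independently distributed codes).

The deletion-order ANOVA treats the animal-averaged performance per
(order, level) cell as a two-way layout without replication: with 5 orders
and 10 levels the order factor has df 4 and the residual (interaction) df 36.
Tukey-Kramer post hoc comparisons of the order means use the studentized
range on the residual mean square.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from dgpop.information import cohens_d

__all__ = [
    "DeletionCurve",
    "EffectSizeMatrix",
    "deletion_order",
    "deletion_curves",
    "pairwise_effect_size",
    "effect_size_matrix",
    "compare_orders_anova",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS = tuple(range(100, 0, -10))  # percent of neurons remaining
EFFECT_SIZE_LEVELS = tuple(range(90, 0, -10))  # nine comparison points


@dataclass
class DeletionCurve:
    """Decoding performance vs percent of neurons remaining, per animal."""

    order_name: str
    percent_remaining: np.ndarray
    performance: np.ndarray  # (n_animals, n_levels)
    metric_name: str = ""

    @property
    def n_animals(self) -> int:
        return self.performance.shape[0]

    def mean_curve(self) -> np.ndarray:
        return self.performance.mean(axis=0)


@dataclass
class EffectSizeMatrix:
    """Pairwise mean |Cohen's d| between deletion orders."""

    orders: list
    mean_abs_d: pd.DataFrame  # orders x orders
    per_pair_d: dict  # (a, b) -> nine d values at 90..10%


def deletion_order(
    order_name: str, scores: dict, n_neurons: int, rng: np.random.Generator
) -> np.ndarray:
    """Deletion sequence (first-deleted first) for a named order.

    ``<score>_desc`` deletes in order of decreasing ``scores[<score>]``
    (highest-scoring neuron removed first), ``<score>_asc`` increasing, and
    ``random`` uniformly at random.  Ties break by neuron index.
    """
    if order_name == "random":
        return rng.permutation(n_neurons)
    for suffix, sign in (("_desc", -1.0), ("_asc", 1.0)):
        if order_name.endswith(suffix):
            key = order_name[: -len(suffix)]
            if key not in scores:
                raise ValueError(f"no ranking score named {key!r} for {order_name!r}")
            s = np.asarray(scores[key], dtype=float)
            if len(s) != n_neurons:
                raise ValueError("ranking score length mismatch")
            return np.argsort(sign * s, kind="stable")
    raise ValueError(f"unknown deletion order {order_name!r}")


def _retained(sequence: np.ndarray, percent: float) -> np.ndarray:
    n = len(sequence)
    keep = max(int(round(n * percent / 100.0)), 1)
    return np.sort(sequence[n - keep :])


def deletion_curves(
    evaluate_subset,
    scores_per_animal: list,
    orders: list,
    levels: tuple = DEFAULT_LEVELS,
    n_random: int = 10,
    seed: int = 0,
    metric_name: str = "",
) -> dict:
    """Compute deletion curves for every order and animal.

    Parameters
    ----------
    evaluate_subset
        Callable ``(animal_index, neuron_indices) -> performance`` that
        retrains the decoder on the given neuron subset and returns the
        out-of-fold metric.
    scores_per_animal
        Per animal, a dict of named per-neuron score arrays (e.g.
        ``{"spatial_info": ..., "speed_info": ...}``) used by ``*_desc`` /
        ``*_asc`` orders.
    orders
        Order names (see :func:`deletion_order`); ``random`` is averaged over
        ``n_random`` independent draws per animal.
    levels
        Percent-remaining levels, descending (100..10 by default).  Deletion
        is nested: each level's neuron set contains the next level's.

    Returns ``{order_name: DeletionCurve}``.
    """
    n_animals = len(scores_per_animal)
    levels = np.asarray(levels, dtype=float)
    curves = {}
    for order_name in orders:
        perf = np.empty((n_animals, len(levels)))
        for a in range(n_animals):
            scores = scores_per_animal[a]
            n_neurons = len(next(iter(scores.values())))
            n_draws = n_random if order_name == "random" else 1
            acc = np.zeros(len(levels))
            for d in range(n_draws):
                name_key = zlib.crc32(order_name.encode()) % 2**31
                rng = np.random.default_rng([seed, a, d, name_key])
                seq = deletion_order(order_name, scores, n_neurons, rng)
                for li, pct in enumerate(levels):
                    acc[li] += evaluate_subset(a, _retained(seq, pct))
            perf[a] = acc / n_draws
        curves[order_name] = DeletionCurve(
            order_name=order_name,
            percent_remaining=levels.copy(),
            performance=perf,
            metric_name=metric_name,
        )
    return curves


def pairwise_effect_size(curve_a: DeletionCurve, curve_b: DeletionCurve):
    """Cohen's d between two orders at the nine levels 90..10% remaining.

    d is computed across animals (unpaired, pooled SD) at each level; the
    summary is the mean of |d| over the nine points.
    """
    if curve_a.n_animals != curve_b.n_animals:
        raise ValueError("curves must share animals")
    if curve_a.n_animals < 2:
        raise ValueError("need at least 2 animals")
    if not np.array_equal(curve_a.percent_remaining, curve_b.percent_remaining):
        raise ValueError("curves must share retention levels")
    d_vals = []
    for pct in EFFECT_SIZE_LEVELS:
        matches = np.flatnonzero(curve_a.percent_remaining == pct)
        if matches.size == 0:
            raise ValueError(f"curves lack the {pct}% retention level")
        li = matches[0]
        d_vals.append(cohens_d(curve_a.performance[:, li], curve_b.performance[:, li]))
    d_vals = np.array(d_vals)
    return d_vals, float(np.mean(np.abs(d_vals)))


def effect_size_matrix(curves: dict) -> EffectSizeMatrix:
    """Symmetric matrix of mean |Cohen's d| over all order pairs."""
    names = list(curves)
    if len(names) < 2:
        raise ValueError("need at least 2 deletion orders")
    mat = pd.DataFrame(0.0, index=names, columns=names)
    per_pair = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d_vals, mean_abs = pairwise_effect_size(curves[a], curves[b])
            mat.loc[a, b] = mat.loc[b, a] = mean_abs
            per_pair[(a, b)] = d_vals
    return EffectSizeMatrix(orders=names, mean_abs_d=mat, per_pair_d=per_pair)


def compare_orders_anova(curves: dict, reference: str = "random") -> dict:
    """Two-way ANOVA of deletion order x retention level, with post hoc tests.

    Performances are averaged across animals per (order, level) cell and
    analysed as a two-way layout without replication: the residual is the
    order x level interaction.  Returns the order and level F statistics with
    their degrees of freedom and Tukey-Kramer pairwise p-values between order
    means (every pair; comparisons against ``reference`` are the ones the
    deletion analysis reports).
    """
    names = list(curves)
    if len(names) < 2:
        raise ValueError("need at least 2 deletion orders")
    n_animals = {c.n_animals for c in curves.values()}
    n_levels = {len(c.percent_remaining) for c in curves.values()}
    if len(n_animals) != 1 or len(n_levels) != 1:
        raise ValueError("unbalanced design: curves differ in animals or levels")
    cell = np.vstack([curves[o].mean_curve() for o in names])  # orders x levels
    k, m = cell.shape
    grand = cell.mean()
    order_means = cell.mean(axis=1)
    level_means = cell.mean(axis=0)
    ss_order = m * np.sum((order_means - grand) ** 2)
    ss_level = k * np.sum((level_means - grand) ** 2)
    resid = cell - order_means[:, None] - level_means[None, :] + grand
    ss_resid = np.sum(resid**2)
    df_order, df_level, df_resid = k - 1, m - 1, (k - 1) * (m - 1)
    # degenerate layouts (identical curves) leave SS at float-noise scale
    scale = max(float(np.sum((cell - grand) ** 2)), np.finfo(float).tiny)
    if ss_resid <= 1e-10 * scale:
        ss_resid = 0.0
    if ss_order <= 1e-10 * scale:
        ss_order = 0.0
    ms_resid = ss_resid / df_resid
    if ms_resid == 0:
        f_order = 0.0 if np.isclose(ss_order, 0) else np.inf
        f_level = 0.0 if np.isclose(ss_level, 0) else np.inf
    else:
        f_order = (ss_order / df_order) / ms_resid
        f_level = (ss_level / df_level) / ms_resid
    from scipy.stats import f as f_dist

    p_order = float(f_dist.sf(f_order, df_order, df_resid)) if np.isfinite(f_order) else 0.0
    if f_order == 0.0:
        p_order = 1.0
    posthoc = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = abs(order_means[i] - order_means[names.index(b)])
            if ms_resid == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = diff / np.sqrt(ms_resid / m)
                p = float(studentized_range.sf(q, k, df_resid))
            posthoc.append({"order_a": a, "order_b": b, "p_tukey": p})
    return {
        "order_F": float(f_order),
        "order_df": (df_order, df_resid),
        "order_p": p_order,
        "level_F": float(f_level),
        "level_df": (df_level, df_resid),
        "posthoc": pd.DataFrame(posthoc),
        "reference": reference,
    }
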
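"""Figure rendering: tuning maps, deletion curves, effect-size heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from dgpop.deletion import EffectSizeMatrix
from dgpop.tuning import SpatialTuningMap

__all__ = ["plot_spatial_map", "plot_deletion_curves", "plot_effect_size_matrix"]


def plot_spatial_map(smap: SpatialTuningMap, path, title: str = "") -> None:
    """Render a normalized spatial tuning map to PNG."""
    fig, ax = plt.subplots(figsize=(4, 4))
    grid = np.ma.masked_invalid(smap.normalized_grid)
    im = ax.imshow(grid, origin="lower", cmap="viridis", vmin=0, vmax=1)
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="rate / max rate")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_deletion_curves(curves: dict, path, metric_name: str = "") -> None:
    """Mean deletion curve per order (x: percent remaining, descending)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        ax.plot(curve.percent_remaining, curve.mean_curve(), marker="o", label=name)
    ax.set_xlabel("% of neurons remaining")
    ax.set_ylabel(metric_name or "decoding performance")
    ax.invert_xaxis()
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_effect_size_matrix(matrix: EffectSizeMatrix, path) -> None:
    """Heatmap of mean |Cohen's d| between deletion orders."""
    fig, ax = plt.subplots(figsize=(5, 4))
    arr = matrix.mean_abs_d.to_numpy()
    im = ax.imshow(arr, cmap="magma")
    ax.set_xticks(range(len(matrix.orders)), matrix.orders, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.orders)), matrix.orders)
    fig.colorbar(im, ax=ax, label="mean |d|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
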
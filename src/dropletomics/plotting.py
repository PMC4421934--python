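"""Figure rendering: fold-change heat maps and factor-score scatter plots.

The heat map follows the profiling convention: red = increased, green =
decreased relative to the across-group mean, black = unchanged (fold 1),
grey = not detected; the colour scale is logarithmic in the fold change and
saturates at the clip bounds.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap, LogNorm  # noqa: E402

__all__ = ["render_heatmap", "render_scores"]

_FOLD_CMAP = LinearSegmentedColormap.from_list(
    "fold", [(0.0, "#00b000"), (0.5, "#000000"), (1.0, "#d00000")])
_FOLD_CMAP.set_bad("#808080")


def render_heatmap(matrix, path, title: str = "") -> Path:
    """Render a HeatmapMatrix to SVG/PNG (suffix decides the format)."""
    folds = matrix.folds
    fig_h = max(2.0, 0.12 * len(folds) + 1.2)
    fig, ax = plt.subplots(figsize=(1.0 + 0.9 * folds.shape[1], fig_h))
    masked = np.ma.masked_invalid(folds.to_numpy(dtype=float))
    im = ax.pcolormesh(masked, cmap=_FOLD_CMAP,
                       norm=LogNorm(vmin=matrix.lo, vmax=matrix.hi))
    ax.set_xticks(np.arange(folds.shape[1]) + 0.5, folds.columns,
                  rotation=45, ha="right", fontsize=7)
    ax.set_yticks(np.arange(len(folds)) + 0.5, folds.index, fontsize=4)
    ax.invert_yaxis()
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="fold change vs across-group mean")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def render_scores(training_scores: pd.DataFrame,
                  training_design: dict[str, str], path,
                  projected_scores: pd.DataFrame | None = None,
                  projected_design: dict[str, str] | None = None,
                  components: tuple[int, int] = (1, 2)) -> Path:
    """Scatter of factor scores: filled markers = training samples,
    empty markers = projected (independent) samples."""
    cx, cy = (f"PC{components[0]}", f"PC{components[1]}")
    groups = sorted(set(training_design.values()))
    colors = plt.cm.tab10(np.linspace(0, 1, max(len(groups), 3)))
    cmap = dict(zip(groups, colors))
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in groups:
        rows = [s for s in training_scores.index
                if training_design.get(s) == g]
        pts = training_scores.loc[rows]
        ycol = pts[cy] if cy in pts else np.zeros(len(pts))
        ax.scatter(pts[cx], ycol, s=45, marker="s", color=cmap[g], label=g)
        ax.scatter([pts[cx].mean()], [np.mean(ycol)], s=120, marker="+",
                   color=cmap[g])
    if projected_scores is not None:
        pdesign = projected_design or {}
        for s in projected_scores.index:
            g = pdesign.get(s)
            color = cmap.get(g, "0.3")
            y = (projected_scores.loc[s, cy]
                 if cy in projected_scores.columns else 0.0)
            ax.scatter([projected_scores.loc[s, cx]], [y], s=45, marker="s",
                       facecolors="none", edgecolors=color)
    ax.set_xlabel(cx)
    ax.set_ylabel(cy)
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
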
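"""Figure exports: importance curves, nose-trajectory fans, PC scatter.

Thin matplotlib wrappers used by the CLI; every function returns the
figure so library users can restyle before saving.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_importance_curves", "plot_trajectory_fan", "plot_pc_scatter"]


def _get_axes(ax):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 3.2), constrained_layout=True)
    return ax.figure, ax


def plot_importance_curves(group_importance, fps_effective: float | None = None, ax=None):
    """Per-group mean frame-importance curves with SEM bands."""
    fig, ax = _get_axes(ax)
    for label in group_importance.labels:
        g = group_importance.groups[label]
        frames = np.arange(1, len(g["mean"]) + 1)
        ax.plot(frames, g["mean"], label=f"{label} (n={g['n']})")
        ax.fill_between(frames, g["mean"] - g["sem"], g["mean"] + g["sem"], alpha=0.25)
    ax.set_xlabel("frame")
    ax.set_ylabel("importance")
    ax.legend(frameon=False)
    if fps_effective:
        sec = ax.secondary_xaxis(
            "top", functions=(lambda f: f / fps_effective, lambda s: s * fps_effective)
        )
        sec.set_xlabel("time (s)")
    return fig


def plot_trajectory_fan(aligned_paths: np.ndarray, labels=None, ax=None):
    """Origin-aligned nose paths, one line per trial (first frame at (0, 0))."""
    fig, ax = _get_axes(ax)
    labels = list(labels) if labels is not None else [None] * len(aligned_paths)
    seen = set()
    palette = {}
    for path, label in zip(aligned_paths, labels):
        if label not in palette:
            palette[label] = f"C{len(palette)}"
        ax.plot(path[:, 0], path[:, 1], color=palette[label], alpha=0.5,
                label=None if label in seen else label)
        seen.add(label)
    ax.scatter([0], [0], color="k", zorder=3, s=15)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_aspect("equal")
    if any(l is not None for l in labels):
        ax.legend(frameon=False)
    return fig


def plot_pc_scatter(pca_result, labels=None, ax=None):
    """Trials in the first two principal components of the measure space."""
    fig, ax = _get_axes(ax)
    scores = pca_result.scores
    if labels is None:
        ax.scatter(scores[:, 0], scores[:, 1], s=12)
    else:
        labels = np.asarray(labels)
        for g in np.unique(labels):
            pts = scores[labels == g]
            ax.scatter(pts[:, 0], pts[:, 1], s=12, label=str(g), alpha=0.7)
        ax.legend(frameon=False)
    evr = pca_result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    return fig
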
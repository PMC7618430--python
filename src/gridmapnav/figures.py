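"""Optional matplotlib renderings of prediction maps and model-fit summaries."""

from __future__ import annotations

import numpy as np

from .experiment import PERFECT


def error_map_figure(pmap, ax=None, vlim=np.pi / 2):
    """Heatmap of a model's signed orientation errors over the test grid.

    Clockwise errors (positive in the compass convention) are drawn dark,
    anticlockwise bright, on a symmetric diverging scale.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    xs = np.unique(pmap.locations[:, 0])
    ys = np.unique(pmap.locations[:, 1])
    # anticlockwise-positive for display
    grid = -pmap.signed_errors.reshape(len(xs), len(ys)).T
    im = ax.pcolormesh(xs, ys, grid, cmap="viridis", vmin=-vlim, vmax=vlim, shading="nearest")
    ax.plot(0, 0, "k.", markersize=8)
    ax.set_aspect("equal")
    ax.set_title(f"{pmap.env_label}: {pmap.model.name}", fontsize=9)
    ax.figure.colorbar(im, ax=ax, label="signed error (rad, anticlockwise +)")
    return ax.figure


def model_fit_figure(summary, ax=None):
    """Bar chart of comparator fits relative to the PERFECT baseline.

    ``summary`` is the output of :func:`gridmapnav.stats.summarize_training`
    for one environment/implementation.  Bars below the dotted baseline
    indicate a comparator that fits the networks better than perfectly
    accurate performance; stars mark the significance annotations.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    checkpoints = sorted(summary.checkpoint.unique())
    comparators = [c for c in summary.comparator.unique() if c != PERFECT]
    width = 0.8 / max(len(comparators), 1)
    for j, comp in enumerate(comparators):
        sub = summary[summary.comparator == comp].set_index("checkpoint")
        heights = [sub.relative_to_perfect.get(c, np.nan) for c in checkpoints]
        pos = np.arange(len(checkpoints)) + (j - (len(comparators) - 1) / 2) * width
        ax.bar(pos, heights, width=width, label=comp)
        for x, c in zip(pos, checkpoints):
            row = sub.loc[c] if c in sub.index else None
            if row is None:
                continue
            if row.stars_vs_perfect:
                ax.text(x, min(row.relative_to_perfect, 0) - 0.02, row.stars_vs_perfect,
                        ha="center", va="top", color="black", fontsize=8)
            if row.stars_vs_next:
                ax.text(x, max(row.relative_to_perfect, 0) + 0.02, row.stars_vs_next,
                        ha="center", va="bottom", color="goldenrod", fontsize=8)
    ax.axhline(0.0, color="black", linestyle=":", linewidth=1)
    ax.set_xticks(np.arange(len(checkpoints)), [str(c) for c in checkpoints])
    ax.set_xlabel("training datapoints (not to scale)")
    ax.set_ylabel("mean abs. difference\nrelative to baseline (rad)")
    ax.legend(fontsize=8)
    ax.figure.tight_layout()
    return ax.figure
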
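"""Static renderings of focus graphs, context silhouettes and binder plots.

These are deliberately simple matplotlib exports (SVG-friendly): node color
encodes the annotation count class, edges point downward from the root,
silhouettes are horizontal per-level bars, and binder plots place terms on a
line ordered by descending node size with alternating level bands and an
optional rejection-frequency heatmap underneath.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dag import AnnotationMap, OntologyDAG
from .layout import BinderOrder, ContextSilhouette, LeveledLayout

__all__ = ["render_focus", "render_silhouette", "render_binder"]

_SIZE_BINS = [1, 10, 100, 1000]
_CMAP = plt.get_cmap("viridis")


def _size_color(size: int) -> tuple:
    cls = int(np.digitize(size, _SIZE_BINS))
    return _CMAP(cls / len(_SIZE_BINS))


def render_focus(
    dag: OntologyDAG, layout: LeveledLayout, ann: AnnotationMap, path: str
) -> None:
    """Node-link drawing of a leveled focus graph, roots on top."""
    pos = {}
    for i, lv in enumerate(layout.levels):
        for j, t in enumerate(lv):
            pos[t] = (j - (len(lv) - 1) / 2.0, -i)
    fig, ax = plt.subplots(figsize=(max(4, len(dag) / 3), max(3, layout.n_levels)))
    for child, parent in dag.edges:
        (x1, y1), (x2, y2) = pos[parent], pos[child]
        ax.plot([x1, x2], [y1, y2], color="0.7", lw=0.8, zorder=1)
    for t, (x, y) in pos.items():
        ax.scatter([x], [y], s=160, color=_size_color(ann.size(t)), zorder=2)
        ax.annotate(t, (x, y), ha="center", va="center", fontsize=6, zorder=3)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def render_silhouette(sil: ContextSilhouette, path: str) -> None:
    """Horizontal bar chart of per-level node counts with highlight overlay."""
    n = len(sil.total_per_level)
    fig, ax = plt.subplots(figsize=(4, max(2, n / 3)))
    y = np.arange(n)
    ax.barh(y, sil.total_per_level, color="0.85", label="all terms")
    ax.barh(y, sil.highlighted_per_level, color="tab:orange", label="related to highlight")
    ax.invert_yaxis()
    ax.set_xlabel("terms per level")
    ax.set_ylabel("level (root = 0)")
    ax.legend(fontsize=7)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def render_binder(
    order: BinderOrder,
    ann: AnnotationMap,
    path: str,
    heatmap: Mapping[str, Mapping[str, float]] | None = None,
    highlight: Iterable[str] = (),
) -> None:
    """Binder plot: linear term sequence with alternating level bands and an
    optional per-condition rejection-frequency heatmap."""
    seq = order.sequence
    n = len(seq)
    conds = list(heatmap) if heatmap else []
    fig, ax = plt.subplots(figsize=(max(4, n / 2.5), 2 + 0.3 * len(conds)))
    bounds = [0, *order.band_boundaries, n]
    for b0, b1, k in zip(bounds, bounds[1:], range(len(bounds))):
        ax.axvspan(b0 - 0.5, b1 - 0.5, color="green", alpha=0.08 + 0.08 * (k % 2))
    hi = set(highlight)
    for i, t in enumerate(seq):
        ax.scatter([i], [0], s=120, color=_size_color(ann.size(t)))
        ax.annotate(
            t, (i, 0.15), rotation=90, ha="center", va="bottom", fontsize=6,
            color="black" if (not hi or t in hi) else "0.6",
        )
    if heatmap:
        mat = np.array([[heatmap[c].get(t, 0.0) for t in seq] for c in conds])
        ax.imshow(
            mat, aspect="auto", cmap="Reds", vmin=0, vmax=1,
            extent=(-0.5, n - 0.5, -0.4 - 0.25 * len(conds), -0.4),
        )
        for k, c in enumerate(conds):
            ax.text(-0.8, -0.4 - 0.25 * (k + 0.5), str(c), ha="right", fontsize=6)
    ax.set_xlim(-1.5, n)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
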
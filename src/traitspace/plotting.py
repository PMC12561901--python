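"""Optional two-dimensional map plots (visualization only).

Requires matplotlib (``pip install traitspace[viz]``).  These figures are a
convenience for eyeballing embedding structure and rating gradients; no
analysis consumes their coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .embeddings import EmbeddingMatrix


def _pca_2d(vectors: np.ndarray) -> np.ndarray:
    centered = vectors - vectors.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ Vt[:2].T


def plot_embedding_map(E: EmbeddingMatrix, values: np.ndarray | None = None,
                       path: str | Path | None = None, title: str = ""):
    """Scatter the items on their first two principal axes.

    ``values`` (e.g. mean ratings, category indices) colors the points.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = _pca_2d(E.vectors)
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, s=12, cmap="viridis")
    if values is not None:
        fig.colorbar(sc, ax=ax)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
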
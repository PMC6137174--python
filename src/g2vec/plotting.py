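"""Optional 2-D visualization of gene representations.

Projects the N x M gene vectors to 2-D with t-SNE and colors genes by
their dominant path-frequency label: mostly-good (blue), mostly-poor
(red), equal counts (yellow), never walked (green).  Best-effort visual
aid; there is no numeric contract on the layout.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.manifold import TSNE

from .embedder import EmbeddingMatrix

logger = logging.getLogger(__name__)

_CATEGORIES = [
    ("good-dominant", "tab:blue"),
    ("poor-dominant", "tab:red"),
    ("equal", "gold"),
    ("never walked", "tab:green"),
]


def _categorize(emb: EmbeddingMatrix, freqs: dict[str, tuple[int, int]]) -> np.ndarray:
    genes = sorted(emb.gene_index, key=emb.gene_index.get)
    cats = np.empty(len(genes), dtype=int)
    for i, g in enumerate(genes):
        good_n, poor_n = freqs.get(g, (0, 0))
        if good_n == 0 and poor_n == 0:
            cats[i] = 3
        elif good_n > poor_n:
            cats[i] = 0
        elif poor_n > good_n:
            cats[i] = 1
        else:
            cats[i] = 2
    return cats


def tsne_coordinates(emb: EmbeddingMatrix, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    perplexity = min(perplexity, max(2.0, (emb.n_genes - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(emb.weights)


def plot_embeddings(
    emb: EmbeddingMatrix,
    freqs: dict[str, tuple[int, int]],
    output_path: str,
    seed: int = 0,
) -> np.ndarray:
    """Write a t-SNE scatter PNG; returns the 2-D coordinates."""
    if not emb.trained_mask.any():
        logger.warning("embedding is untrained; plot will show only initial vectors")
    coords = tsne_coordinates(emb, seed=seed)
    cats = _categorize(emb, freqs)
    fig, ax = plt.subplots(figsize=(6, 6))
    for idx, (label, color) in enumerate(_CATEGORIES):
        mask = cats == idx
        ax.scatter(coords[mask, 0], coords[mask, 1], s=8, c=color, label=label)
    ax.legend(loc="best", fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title("Distributed gene representations")
    fig.tight_layout()
    fig.savefig(output_path, dpi=120)
    plt.close(fig)
    return coords
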
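"""Single-cell 2-D embeddings of standard-score profiles.

t-SNE (default perplexity 100, matching the study protocol) and UMAP views
of the per-cell score matrix, plus a silhouette-based separation summary
quantifying how distinct the senescent population is from the
proliferating one in embedding space.  Runs are seed-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

DEFAULT_PERPLEXITY = 100.0


@dataclass
class Embedding2D:
    coords: np.ndarray          # (n, 2)
    algorithm: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coordinates must be (n, 2)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite embedding coordinates")

    def to_frame(self, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=["x", "y"])
        if metadata is not None:
            df = pd.concat([metadata.reset_index(drop=True), df], axis=1)
        return df


def _score_matrix(scores: pd.DataFrame, features: list[str]) -> np.ndarray:
    x = scores[features].to_numpy(float)
    return np.nan_to_num(x)


def tsne_embed(
    scores: pd.DataFrame,
    features: list[str],
    perplexity: float = DEFAULT_PERPLEXITY,
    seed: int = 0,
) -> Embedding2D:
    x = _score_matrix(scores, features)
    n = x.shape[0]
    if n < 10:
        raise ValueError("refusing t-SNE on fewer than 10 cells")
    if n <= 3 * perplexity:
        new = max(5.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {perplexity} too large for n={n}; lowered to {new:.0f}",
            stacklevel=2,
        )
        perplexity = new
    ts = TSNE(
        n_components=2, perplexity=perplexity, init="pca", random_state=seed
    )
    coords = ts.fit_transform(x)
    return Embedding2D(coords, "tsne", {"perplexity": perplexity}, seed)


def umap_embed(
    scores: pd.DataFrame,
    features: list[str],
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> Embedding2D:
    import umap  # deferred: numba compilation makes this import heavy

    x = _score_matrix(scores, features)
    if x.shape[0] < 10:
        raise ValueError("refusing UMAP on fewer than 10 cells")
    n_neighbors = min(n_neighbors, x.shape[0] - 1)
    um = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    coords = um.fit_transform(x)
    return Embedding2D(
        coords, "umap", {"n_neighbors": n_neighbors, "min_dist": min_dist}, seed
    )


def separation_score(embedding: Embedding2D, labels) -> float:
    """Mean silhouette of condition labels in embedding space, in [-1, 1]."""
    labels = np.asarray(labels)
    if len(labels) != len(embedding.coords):
        raise ValueError("label count does not match embedding size")
    if len(np.unique(labels)) < 2:
        raise ValueError("separation needs at least two distinct labels")
    return float(silhouette_score(embedding.coords, labels))


def plot_embedding(
    embedding: Embedding2D, labels, path, senescent_label: str | None = None
) -> None:
    """Scatter coloured blue (proliferating) / orange (senescent)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    colors = {}
    for u in uniq:
        sen = senescent_label == u if senescent_label else "sen" in str(u).lower()
        colors[u] = "tab:orange" if sen else "tab:blue"
    fig, ax = plt.subplots(figsize=(5, 5))
    for u in uniq:
        m = labels == u
        ax.scatter(*embedding.coords[m].T, s=4, alpha=0.6, label=str(u), c=colors[u])
    ax.set_xlabel(f"{embedding.algorithm} 1")
    ax.set_ylabel(f"{embedding.algorithm} 2")
    ax.legend(markerscale=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
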
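"""Tanimoto-distance t-SNE embedding of fingerprint space.

The pairwise Tanimoto distance matrix of a fingerprint dataset is embedded
into two dimensions with t-SNE (precomputed-distance mode, perplexity 30 by
default, random initialization under a fixed seed). The embedding serves
representation-space visualization: how clearly the binding-mode classes
separate in interaction-fingerprint versus atom-environment space. The mean
silhouette coefficient of the 2D coordinates with respect to the true
labels is used as a quantitative proxy for that visual separation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.manifold import TSNE

from .modes import BindingMode


@dataclasses.dataclass(frozen=True)
class EmbeddingConfig:
    perplexity: float = 30.0
    seed: int = 0
    n_components: int = 2  # fixed; kept as a field for config echoing

    def __post_init__(self) -> None:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.n_components != 2:
            raise ValueError("only 2-D embeddings are supported")


@dataclasses.dataclass
class Embedding2D:
    coordinates: np.ndarray  # (n, 2)
    inhibitor_ids: list[str]
    labels: list[BindingMode]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.inhibitor_ids), 2):
            raise ValueError("coordinates must be n x 2 and row-aligned")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite embedding coordinates")


def tsne_embed(
    dmat: np.ndarray,
    config: EmbeddingConfig,
    inhibitor_ids: list[str] | None = None,
    labels: list[BindingMode] | None = None,
) -> Embedding2D:
    """Embed a precomputed symmetric distance matrix into 2-D with t-SNE."""
    dmat = np.asarray(dmat, dtype=float)
    n = dmat.shape[0]
    if dmat.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.isfinite(dmat).all():
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(dmat, dmat.T):
        raise ValueError("distance matrix is not symmetric")
    if config.perplexity >= n - 1:
        raise ValueError(f"perplexity {config.perplexity} too large for n={n}")
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        perplexity=config.perplexity,
        init="random",
        random_state=config.seed,
    )
    coords = tsne.fit_transform(dmat)
    return Embedding2D(
        coordinates=coords,
        inhibitor_ids=inhibitor_ids or [f"row{i}" for i in range(n)],
        labels=list(labels) if labels else [],
    )


def embedding_silhouette(embedding: Embedding2D) -> float:
    """Mean silhouette of the 2-D coordinates w.r.t. the binding-mode labels."""
    from sklearn.metrics import silhouette_score

    if not embedding.labels:
        raise ValueError("embedding carries no labels")
    return float(
        silhouette_score(embedding.coordinates, [m.value for m in embedding.labels])
    )
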
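"""Low-dimensional embedding QC and the cohort separation statistic.

Cohorts are flattened to observation × voxel matrices and embedded in two
dimensions with t-SNE (perplexity 30, early exaggeration 12, learning rate
200, 1000 iterations by default). The separation statistic — a mean
silhouette over a two-group labeling — quantifies how much more tightly a
stereotyped lesion cohort clusters than its matched pseudo-random cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

__all__ = ["EmbeddingResult", "flatten_maps", "unflatten_map", "embed_2d", "separation_statistic"]


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # observations x 2
    labels: list | None
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite embedding coordinates")
        if self.labels is not None and len(self.labels) != self.coordinates.shape[0]:
            raise ValueError("one label per observation required")


def flatten_maps(maps, mask: np.ndarray) -> np.ndarray:
    """Row per map, column per in-mask voxel (C-order voxel ordering)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows = []
    for i, m in enumerate(maps):
        vol = np.asarray(m, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError(f"map {i} grid mismatch")
        rows.append(vol[mask])
    return np.stack(rows)


def unflatten_map(row: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    out = np.full(mask.shape, fill, dtype=float)
    out[mask] = row
    return out


def embed_2d(
    matrix: np.ndarray,
    perplexity: float = 30.0,
    exaggeration: float = 12.0,
    learning_rate: float = 200.0,
    iterations: int = 1000,
    seed: int = 0,
    labels=None,
) -> EmbeddingResult:
    """2-D t-SNE of an observation × feature matrix, deterministic under seed.

    Exaggeration is applied as early exaggeration (the standard scheme).
    Perplexity is auto-shrunk with a warning when the cohort is small.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 observations to embed")
    eff_perplexity = perplexity
    if n <= 3 * perplexity:
        eff_perplexity = max(2.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {perplexity} too large for n={n}; shrunk to {eff_perplexity:.1f}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=eff_perplexity,
        early_exaggeration=exaggeration,
        learning_rate=learning_rate,
        max_iter=iterations,
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(X)
    return EmbeddingResult(
        coordinates=coords,
        labels=list(labels) if labels is not None else None,
        settings={
            "perplexity": eff_perplexity,
            "requested_perplexity": perplexity,
            "exaggeration": exaggeration,
            "learning_rate": learning_rate,
            "iterations": iterations,
            "seed": seed,
        },
    )


def separation_statistic(X: np.ndarray, labels) -> float:
    """Mean silhouette of a two-group labeling; higher = tighter groups.

    Accepts either the raw observation × feature matrix or 2-D embedding
    coordinates; distances are Euclidean.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size != 2:
        raise ValueError(f"exactly two groups required, got {groups.size}")
    if counts.min() < 2:
        raise ValueError("both groups need at least 2 observations")
    return float(silhouette_samples(X, labels).mean())


def plot_embedding(result: EmbeddingResult, path) -> None:
    """Scatter of the embedding, coloured by label."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    labels = result.labels if result.labels is not None else ["all"] * len(result.coordinates)
    for lab in sorted(set(labels)):
        sel = np.asarray([l == lab for l in labels])
        ax.scatter(result.coordinates[sel, 0], result.coordinates[sel, 1], s=8, label=str(lab))
    ax.legend(frameon=False)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
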
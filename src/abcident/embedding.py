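"""2-D t-SNE visualization of feature matrices.

Defaults follow the settings used to inspect 188D feature separability:
2 output dimensions, perplexity 10, theta 0 (exact, non-Barnes-Hut
gradients), 1000 iterations, early-exaggeration factor 8.  The
early-exaggeration duration is the solver default.  Features are embedded
raw by default (they already live in [0, 1]); standardization is optional.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.manifold import TSNE

from .features import FeatureMatrix
from .seq_io import Label


@dataclass(frozen=True)
class TSNESettings:
    """t-SNE hyperparameters.  theta = 0 selects exact gradient computation."""

    dims: int = 2
    perplexity: float = 10.0
    theta: float = 0.0
    max_iter: int = 1000
    exaggeration_factor: float = 8.0

    def __post_init__(self) -> None:
        if self.dims < 1:
            raise ValueError("dims must be >= 1")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.max_iter < 250:
            raise ValueError("max_iter must be >= 250")


@dataclass
class EmbeddingResult:
    """Low-dimensional coordinates with provenance (settings, seed, final KL)."""

    coordinates: np.ndarray
    ids: list[str]
    labels: Optional[list[Label]]
    settings: TSNESettings
    seed: int
    kl_divergence: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tlabel\tx\ty\n")
            for i, rid in enumerate(self.ids):
                label = self.labels[i].value if self.labels is not None else ""
                coords = "\t".join(f"{v:.10g}" for v in self.coordinates[i])
                fh.write(f"{rid}\t{label}\t{coords}\n")

    def write_settings_json(self, path: str | Path) -> None:
        payload = {
            "settings": asdict(self.settings),
            "seed": self.seed,
            "kl_divergence": self.kl_divergence,
            "n": len(self.ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def plot(self, path: str | Path) -> None:
        """Scatter plot colored by label (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        if self.labels is not None:
            for label in sorted({l.value for l in self.labels}):
                mask = [l.value == label for l in self.labels]
                ax.scatter(
                    self.coordinates[mask, 0],
                    self.coordinates[mask, 1],
                    s=8,
                    label=label,
                    alpha=0.7,
                )
            ax.legend()
        else:
            ax.scatter(self.coordinates[:, 0], self.coordinates[:, 1], s=8)
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def tsne_embed(
    matrix: FeatureMatrix,
    settings: TSNESettings = TSNESettings(),
    seed: int = 42,
    standardize: bool = False,
    jitter: float = 0.0,
) -> EmbeddingResult:
    """Embed a feature matrix into ``settings.dims`` dimensions with t-SNE.

    Deterministic for a fixed seed.  ``jitter`` adds seeded Gaussian noise
    of that standard deviation, useful when duplicate rows would collapse
    neighborhoods.  Requires n >= 3 * perplexity for a valid perplexity.
    """
    n = len(matrix)
    min_n = int(np.ceil(3 * settings.perplexity))
    if n < min_n:
        raise ValueError(
            f"t-SNE with perplexity {settings.perplexity} needs at least "
            f"{min_n} samples, got {n}"
        )
    X = matrix.X
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    if jitter > 0:
        X = X + np.random.default_rng(seed).normal(scale=jitter, size=X.shape)
    method = "exact" if settings.theta == 0.0 else "barnes_hut"
    tsne = TSNE(
        n_components=settings.dims,
        perplexity=settings.perplexity,
        early_exaggeration=settings.exaggeration_factor,
        max_iter=settings.max_iter,
        method=method,
        angle=settings.theta if settings.theta > 0 else 0.5,
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(X)
    return EmbeddingResult(
        coordinates=np.asarray(coords, dtype=float),
        ids=list(matrix.ids),
        labels=list(matrix.labels) if matrix.labels is not None else None,
        settings=settings,
        seed=seed,
        kl_divergence=float(tsne.kl_divergence_),
    )


def neighbor_label_purity(result: EmbeddingResult, k: int = 10) -> float:
    """Mean fraction of each point's k nearest embedded neighbors sharing its label.

    A label-relative statistic: invariant to translation, rotation and
    scaling of the embedding.
    """
    if result.labels is None:
        raise ValueError("embedding carries no labels")
    from sklearn.neighbors import NearestNeighbors

    coords = result.coordinates
    labels = np.array([l.value for l in result.labels])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neighbor_labels = labels[idx[:, 1:]]  # drop self
    return float(np.mean(neighbor_labels == labels[:, None]))
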
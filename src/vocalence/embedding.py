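"""t-SNE maps of classifier activations.

After training, the activations of the last hidden fully connected layer
are projected to 2-D with t-SNE to visualize how the network organizes
the calls: one map colored by valence (default perplexity 50) and one by
context (default perplexity 20).  Negative-valence calls are drawn as
triangles, positive as circles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

__all__ = ["EmbeddingResult", "extract_activations", "embed", "plot_embedding",
           "DEFAULT_PERPLEXITY"]

DEFAULT_PERPLEXITY = {"valence": 50.0, "context": 20.0}


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # n x 2
    valence: np.ndarray
    context: np.ndarray
    perplexity: float
    rng_seed: int

    def to_frame(self, call_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.coords[:, 0], "y": self.coords[:, 1],
                           "valence": self.valence, "context": self.context})
        if call_ids is not None:
            df.insert(0, "call_id", list(call_ids))
        return df


def extract_activations(model, X: np.ndarray) -> np.ndarray:
    """One penultimate-layer activation vector per spectrogram."""
    if not hasattr(model, "penultimate"):
        raise TypeError("model has no penultimate fully connected layer")
    return model.penultimate(X)


def embed(activations: np.ndarray, perplexity: float, rng_seed: int = 0,
          valence=None, context=None) -> EmbeddingResult:
    """Standard 2-D t-SNE, deterministic for a given seed (PCA init)."""
    n = activations.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n = {n}")
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=rng_seed)
    coords = tsne.fit_transform(np.asarray(activations, np.float64))
    empty = np.array([""] * n, dtype=object)
    return EmbeddingResult(
        coords=np.asarray(coords, float),
        valence=np.asarray(valence, dtype=object) if valence is not None else empty,
        context=np.asarray(context, dtype=object) if context is not None else empty,
        perplexity=float(perplexity), rng_seed=int(rng_seed),
    )


def plot_embedding(result: EmbeddingResult, color_by: str = "valence", path=None):
    """Scatter map: triangles = negative valence, circles = positive."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    labels = getattr(result, color_by)
    uniq = sorted(set(labels))
    cmap = plt.get_cmap("tab20")
    colors = {l: cmap(i % 20) for i, l in enumerate(uniq)}
    for neg, marker in (("negative", "^"), ("positive", "o")):
        sel = result.valence == neg
        if not np.any(sel):
            continue
        ax.scatter(result.coords[sel, 0], result.coords[sel, 1],
                   c=[colors[l] for l in labels[sel]], marker=marker,
                   s=18, alpha=0.8, linewidths=0)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title(f"t-SNE of last-layer activations (perplexity={result.perplexity:g})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
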
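"""Fixed-seed 2-D embedding of activity vectors for figures.

A thin wrapper over t-SNE; used for visualization only — no quantitative
claims are attached to the embedded coordinates.
"""

from __future__ import annotations

import numpy as np
from sklearn.manifold import TSNE

__all__ = ["embed_2d"]


def embed_2d(vectors: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D t-SNE coordinates, deterministic given ``seed``."""
    X = np.asarray(vectors, dtype=float)
    if len(X) < 5:
        raise ValueError("need at least 5 vectors to embed")
    perplexity = min(30.0, (len(X) - 1) / 3.0)
    ts = TSNE(
        n_components=2,
        random_state=seed,
        init="pca",
        perplexity=perplexity,
    )
    return ts.fit_transform(X)
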
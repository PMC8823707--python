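"""2-D t-SNE map of kinetic behavior.

The embedding is computed exactly (no Barnes-Hut approximation) at
perplexity 50 by default, from the complete-case profile matrix.  The
layout is reproducible in structure given a seed, but, like any t-SNE,
not in orientation; initialization is deterministic PCA to reduce
run-to-run topology variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment, KMeansResult, _labels_of
from .quant import QuantMatrix


@dataclass
class Embedding2D:
    """Per-protein 2-D coordinates plus the parameters that produced them."""

    coords: pd.DataFrame  # protein -> (tsne_x, tsne_y)
    perplexity: float
    theta: float
    seed: int
    n_iter: int

    def __post_init__(self) -> None:
        if list(self.coords.columns) != ["tsne_x", "tsne_y"]:
            raise ValueError("coordinates must have columns tsne_x, tsne_y")
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValueError("non-finite embedding coordinates")

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.coords.to_csv(path, sep="\t", index_label="protein_id")
        return path


def tsne_embed(
    m: QuantMatrix | np.ndarray,
    perplexity: float = 50.0,
    theta: float = 0.0,
    seed: int = 0,
    n_iter: int = 1000,
    index: pd.Index | None = None,
) -> Embedding2D:
    """Embed complete kinetic profiles in two dimensions by t-SNE.

    ``theta = 0`` requests the exact gradient (no approximation); positive
    values use Barnes-Hut with that angle.  Feasibility requires
    ``n >= 3 * perplexity + 1``.
    """
    from sklearn.manifold import TSNE

    if isinstance(m, QuantMatrix):
        if not m.is_complete():
            raise ValueError("t-SNE requires a complete matrix")
        x = m.values()
        index = m.proteins
    else:
        x = np.asarray(m, dtype=float)
        if index is None:
            index = pd.RangeIndex(x.shape[0])
    n = x.shape[0]
    min_n = int(3 * perplexity + 1)
    if n < min_n:
        raise ValueError(
            f"perplexity {perplexity} infeasible for n={n}: need n >= 3*perplexity+1 = {min_n}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        method="exact" if theta == 0 else "barnes_hut",
        angle=theta if theta > 0 else 0.5,
        init="pca",
        random_state=seed,
        max_iter=n_iter,
    )
    emb = tsne.fit_transform(x)
    coords = pd.DataFrame(emb, index=index, columns=["tsne_x", "tsne_y"])
    return Embedding2D(coords=coords, perplexity=perplexity, theta=theta, seed=seed, n_iter=n_iter)


def overlay_clusters(
    e: Embedding2D, a: ClusterAssignment | KMeansResult | pd.Series
) -> pd.DataFrame:
    """Join embedding coordinates with cluster names for plotting/export.

    Raises
    ------
    ValueError
        If the protein sets of the embedding and the assignment differ.
    """
    labels = _labels_of(a)
    if set(labels.index) != set(e.coords.index):
        raise ValueError("embedding and cluster assignment cover different protein sets")
    out = e.coords.copy()
    out["cluster"] = labels.reindex(out.index)
    return out
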
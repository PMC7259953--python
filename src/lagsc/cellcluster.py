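"""Cell subpopulation discovery: PCA embedding plus k-means.

Cells are embedded by PCA of the gene-standardized normalized expression
(genes centered and unit-scaled, with a zero-variance guard) and partitioned
by k-means with an explicit cluster count ``k``. Explicit k replaces
graph-based clustering with a tuned resolution knob: the analysis goal —
recovering a known number of transcriptional subgroups — is testable with
any consistent partitioner, and explicit k makes the run reproducible.

Evaluation against known labels should use label-permutation-invariant
scores (adjusted Rand index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .normalize import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterParams:
    n_components: int = 10
    k: int = 4
    n_init: int = 10
    seed: int = 0
    highly_variable_n: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass
class ClusterAssignment:
    """Cluster ids (1..k) per cell, with centroids and final inertia."""

    labels: np.ndarray  # int, 1-based, one per cell
    centroids: np.ndarray
    inertia: float
    barcodes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, int]:
        return {b: int(l) for b, l in zip(self.barcodes, self.labels)}


def pca_embed(
    nm: NormalizedMatrix,
    n_components: int = 10,
    highly_variable_n: int | None = None,
) -> np.ndarray:
    """Cells x components PCA embedding of standardized expression.

    Genes are centered and scaled to unit variance (zero-variance genes are
    left centered only). ``highly_variable_n`` optionally restricts to the
    top-variance genes first. If ``n_components`` exceeds the data rank it is
    reduced with a warning.
    """
    if nm.n_cells < 2:
        raise ValueError("need at least 2 cells to embed")
    x = nm.values.T.copy()  # cells x genes
    if highly_variable_n is not None and highly_variable_n < x.shape[1]:
        var = x.var(axis=0)
        top = np.argsort(var)[::-1][:highly_variable_n]
        x = x[:, np.sort(top)]
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_components > max_rank:
        logger.warning(
            "n_components=%d exceeds data rank %d; reduced", n_components, max_rank
        )
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(x)


def kmeans_cells(
    embedding: np.ndarray,
    params: ClusterParams,
    barcodes: list[str] | None = None,
) -> ClusterAssignment:
    """k-means (k-means++ init, best of n_init seeded restarts by inertia)."""
    embedding = np.asarray(embedding, dtype=float)
    n_cells = embedding.shape[0]
    if params.k > n_cells:
        raise ValueError(f"k={params.k} exceeds the number of cells ({n_cells})")
    km = KMeans(
        n_clusters=params.k,
        init="k-means++",
        n_init=params.n_init,
        random_state=params.seed,
    )
    labels = km.fit_predict(embedding) + 1
    return ClusterAssignment(
        labels=labels.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        barcodes=list(barcodes) if barcodes is not None else [],
    )


def cluster_cells(nm: NormalizedMatrix, params: ClusterParams) -> ClusterAssignment:
    """Convenience wrapper: PCA embed then k-means, keeping barcodes attached."""
    emb = pca_embed(nm, params.n_components, params.highly_variable_n)
    return kmeans_cells(emb, params, barcodes=nm.barcodes)
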
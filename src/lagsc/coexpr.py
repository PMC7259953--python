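"""Co-expression network construction and module detection.

Pipeline: (1) drop genes with fewer than ``min_total_umi`` raw UMIs summed
across the population; (2) compute all pairwise Pearson correlations of the
normalized expression vectors across cells, with two-sided p-values from the
t transform ``t = r * sqrt((n - 2) / (1 - r^2))``; (3) Bonferroni-adjust over
the number of tested unordered pairs; (4) keep an edge when |r| >=
``min_abs_r`` and adjusted p <= ``alpha``; (5) drop genes with fewer than
``min_partners`` significant edges (degrees frozen before removal under
``single_pass``; recomputed to a fixed point under ``iterative``); (6) zero
the identity diagonal; (7) cluster the rows of the retained correlation
matrix into ``n_modules`` modules (agglomerative on Euclidean distance
between correlation-row vectors by default, k-means optionally).

Zero-variance genes get r = 0, p = 1 and therefore never form edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.stats
from sklearn.cluster import KMeans

from .counts_io import CountMatrix
from .exceptions import InsufficientDataError
from .normalize import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class CoexprParams:
    """Gene/edge filters and clustering knobs for the network build."""

    min_total_umi: int = 10
    min_partners: int = 7
    min_abs_r: float = 0.1
    alpha: float = 0.05
    n_modules: int = 6
    linkage: str = "average"  # average | complete | ward
    pruning: str = "single_pass"  # single_pass | iterative
    cluster_method: str = "hierarchical"  # hierarchical | kmeans
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_abs_r < 1:
            raise ValueError("min_abs_r must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_modules < 1:
            raise ValueError("n_modules must be positive")
        if self.linkage not in ("average", "complete", "ward"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.pruning not in ("single_pass", "iterative"):
            raise ValueError(f"unknown pruning {self.pruning!r}")
        if self.cluster_method not in ("hierarchical", "kmeans"):
            raise ValueError(f"unknown cluster_method {self.cluster_method!r}")


@dataclass
class CoexpressionNetwork:
    """Retained genes with correlations, significant edges and modules."""

    retained_genes: list[str]
    corr: np.ndarray  # symmetric, zero diagonal
    signif_edges: np.ndarray  # boolean, symmetric, zero diagonal
    degrees: np.ndarray  # per retained gene
    modules: dict[str, int] = field(default_factory=dict)  # gene -> 1..n_modules
    n_pairs_tested: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.retained_genes)

    def edge_list(self, p: np.ndarray | None = None) -> pd.DataFrame:
        """Significant edges as a tidy (gene1, gene2, r) table."""
        rows = []
        for i in range(self.n_genes):
            for j in range(i + 1, self.n_genes):
                if self.signif_edges[i, j]:
                    rows.append(
                        (self.retained_genes[i], self.retained_genes[j], self.corr[i, j])
                    )
        return pd.DataFrame(rows, columns=["gene1", "gene2", "r"])


def pairwise_pearson(
    nm: NormalizedMatrix, genes: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p across cells.

    Returns ``(corr, p, zero_variance)`` where ``zero_variance`` flags genes
    with constant expression (these get r = 0 against everything, p = 1).
    The diagonal of ``corr`` is 1 for non-degenerate genes (zeroing the
    identity diagonal is the network builder's step, not this function's).
    """
    if genes is None:
        genes = nm.gene_ids
    idx = [nm.gene_ids.index(g) for g in genes]
    values = nm.values[idx, :]
    n_cells = values.shape[1]
    if n_cells < 3:
        raise InsufficientDataError("need at least 3 cells for correlation p-values")
    sd = values.std(axis=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, np.where(zero_var, 0.0, 1.0))
    corr = np.clip(corr, -1.0, 1.0)

    r = corr.copy()
    np.fill_diagonal(r, 0.0)  # avoid division blow-up; diagonal p set below
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n_cells - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n_cells - 2)
    np.fill_diagonal(p, 0.0)
    p[zero_var, :] = 1.0
    p[:, zero_var] = 1.0
    return corr, p, zero_var


def build_network(
    nm: NormalizedMatrix, cm: CountMatrix, params: CoexprParams | None = None
) -> CoexpressionNetwork:
    """Run the full filter -> correlate -> prune -> cluster pipeline."""
    if params is None:
        params = CoexprParams()
    if nm.gene_ids != cm.gene_ids:
        raise ValueError("normalized matrix and count matrix gene universes differ")

    totals = cm.counts.sum(axis=1)
    umi_pass = [g for g, t in zip(cm.gene_ids, totals) if t >= params.min_total_umi]
    if len(umi_pass) < 2:
        logger.info("no gene pair survives the UMI filter; empty network")
        return CoexpressionNetwork(umi_pass, np.zeros((len(umi_pass),) * 2),
                                   np.zeros((len(umi_pass),) * 2, dtype=bool),
                                   np.zeros(len(umi_pass), dtype=int))

    corr, p, _ = pairwise_pearson(nm, umi_pass)
    m = len(umi_pass)
    n_pairs = m * (m - 1) // 2
    p_adj = np.minimum(1.0, p * n_pairs)  # Bonferroni over unordered tested pairs
    edges = (np.abs(corr) >= params.min_abs_r) & (p_adj <= params.alpha)
    np.fill_diagonal(edges, False)
    edges &= edges.T  # symmetry guard (already symmetric by construction)

    keep = np.ones(m, dtype=bool)
    if params.pruning == "single_pass":
        degrees = edges.sum(axis=1)
        keep = degrees >= params.min_partners
    else:
        while True:
            degrees = (edges & keep[np.newaxis, :] & keep[:, np.newaxis]).sum(axis=1)
            new_keep = keep & (degrees >= params.min_partners)
            if (new_keep == keep).all():
                break
            keep = new_keep

    retained = [g for g, k in zip(umi_pass, keep) if k]
    sub = np.flatnonzero(keep)
    corr_r = corr[np.ix_(sub, sub)].copy()
    edges_r = edges[np.ix_(sub, sub)].copy()
    np.fill_diagonal(corr_r, 0.0)
    # degrees as used by the filter decision (pre-prune gene set)
    deg_r = edges.sum(axis=1)[sub]

    modules: dict[str, int] = {}
    k = len(retained)
    if k:
        n_mod = min(params.n_modules, k)
        if n_mod == 1 or k == 1:
            labels = np.ones(k, dtype=int)
        elif params.cluster_method == "kmeans":
            km = KMeans(n_clusters=n_mod, n_init=10, random_state=params.seed)
            labels = km.fit_predict(corr_r) + 1
        else:
            method = params.linkage
            z = scipy.cluster.hierarchy.linkage(corr_r, method=method, metric="euclidean")
            labels = scipy.cluster.hierarchy.fcluster(z, t=n_mod, criterion="maxclust")
        modules = {g: int(l) for g, l in zip(retained, labels)}
    else:
        logger.info("no gene survives the degree filter; empty network")

    return CoexpressionNetwork(
        retained_genes=retained,
        corr=corr_r,
        signif_edges=edges_r,
        degrees=deg_r.astype(int),
        modules=modules,
        n_pairs_tested=n_pairs,
    )


def best_match_jaccard(
    modules: dict[str, int], truth: dict[str, set[str]]
) -> dict[str, float]:
    """Best-matching Jaccard index of each truth module against found modules.

    Label-invariant: every truth gene set is compared against every found
    module and the best overlap is reported.
    """
    found: dict[int, set[str]] = {}
    for g, m in modules.items():
        found.setdefault(m, set()).add(g)
    out = {}
    for name, genes in truth.items():
        best = 0.0
        for fg in found.values():
            inter = len(genes & fg)
            union = len(genes | fg)
            if union:
                best = max(best, inter / union)
        out[name] = best
    return out
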
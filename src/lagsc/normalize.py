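"""Depth normalization and log transform of UMI counts.

Each cell's counts are scaled to a common library size (``scale_factor``,
default 10,000) and transformed as ``ln(1 + scale_factor * count / total)``.
Cells with zero total counts are retained with all-zero columns; dropping
degenerate cells is the QC module's job, not the normalizer's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts_io import CountMatrix


@dataclass
class NormalizedMatrix:
    """Log-normalized expression paired to its source CountMatrix."""

    values: np.ndarray  # genes x cells, float
    scale_factor: float
    source: CountMatrix

    @property
    def gene_ids(self) -> list[str]:
        return self.source.gene_ids

    @property
    def barcodes(self) -> list[str]:
        return self.source.barcodes

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def log_normalize(cm: CountMatrix, scale_factor: float = 10000.0) -> NormalizedMatrix:
    """Per-cell depth scaling followed by log1p.

    ``value(g, c) = ln(1 + scale_factor * count(g, c) / total_umi(c))``;
    zero-total cells map to zero columns.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = cm.counts.sum(axis=0).astype(float)
    safe_totals = np.where(totals > 0, totals, 1.0)
    scaled = scale_factor * cm.counts / safe_totals[np.newaxis, :]
    values = np.log1p(scaled)
    values[:, totals == 0] = 0.0
    return NormalizedMatrix(values=values, scale_factor=float(scale_factor), source=cm)
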
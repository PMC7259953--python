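"""Per-cell quality control: detected-gene and mitochondrial-fraction caps.

Droplets carrying two cells show unusually many detected genes; droplets
carrying dying cells show a high share of mitochondrial reads. Both are
removed by strict upper bounds: a cell is discarded when its detected-gene
count or its mitochondrial percentage strictly exceeds the configured
maximum (cells sitting exactly at a threshold are kept). No lower bound is
applied; empty-droplet removal is an upstream (barcode-calling) concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts_io import CountMatrix


@dataclass
class QCThresholds:
    """Upper bounds for per-cell QC.

    ``max_mito_pct`` is interpreted on the percent scale (0.2 means 0.2%).
    Set ``mito_pct_is_fraction=True`` to interpret the same number as a
    fraction instead (0.2 means 20%).
    """

    max_genes_detected: int
    max_mito_pct: float
    mito_pct_is_fraction: bool = False

    def __post_init__(self) -> None:
        if self.max_genes_detected <= 0:
            raise ValueError("max_genes_detected must be positive")
        if self.max_mito_pct < 0:
            raise ValueError("max_mito_pct must be non-negative")
        limit = 1.0 if self.mito_pct_is_fraction else 100.0
        if self.max_mito_pct > limit:
            raise ValueError(f"max_mito_pct must be <= {limit}")

    @property
    def mito_pct_bound(self) -> float:
        """The mito bound on the percent scale regardless of input scale."""
        return self.max_mito_pct * 100.0 if self.mito_pct_is_fraction else self.max_mito_pct


@dataclass
class QCReport:
    """Outcome of a QC pass: survivors, casualties with reasons, and stats."""

    kept_barcodes: list[str]
    removed_barcodes: list[str]
    removal_reasons: dict[str, str]
    per_cell_stats: pd.DataFrame  # index barcode; genes_detected, total_umi, mito_pct


def cell_stats(cm: CountMatrix) -> pd.DataFrame:
    """Per-cell (genes_detected, total_umi, mito_pct), indexed by barcode.

    ``mito_pct`` is 100 x mito UMIs / total UMIs, defined as 0 for cells with
    zero total counts.
    """
    genes_detected = (cm.counts > 0).sum(axis=0)
    total_umi = cm.counts.sum(axis=0)
    mito_umi = cm.counts[cm.mito_flags].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_pct = np.where(total_umi > 0, 100.0 * mito_umi / np.maximum(total_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "genes_detected": genes_detected.astype(int),
            "total_umi": total_umi.astype(int),
            "mito_pct": mito_pct.astype(float),
        },
        index=pd.Index(cm.barcodes, name="barcode"),
    )


def apply_qc(cm: CountMatrix, th: QCThresholds) -> tuple[CountMatrix, QCReport]:
    """Remove cells exceeding either threshold; the gene set is unchanged."""
    stats = cell_stats(cm)
    too_many_genes = stats["genes_detected"].to_numpy() > th.max_genes_detected
    too_much_mito = stats["mito_pct"].to_numpy() > th.mito_pct_bound
    removed = too_many_genes | too_much_mito
    reasons: dict[str, str] = {}
    for i, bc in enumerate(cm.barcodes):
        if too_many_genes[i] and too_much_mito[i]:
            reasons[bc] = "genes_detected;mito_pct"
        elif too_many_genes[i]:
            reasons[bc] = "genes_detected"
        elif too_much_mito[i]:
            reasons[bc] = "mito_pct"
    kept = ~removed
    filtered = cm.subset_cells(kept)
    report = QCReport(
        kept_barcodes=[b for b, k in zip(cm.barcodes, kept) if k],
        removed_barcodes=[b for b, r in zip(cm.barcodes, removed) if r],
        removal_reasons=reasons,
        per_cell_stats=stats,
    )
    return filtered, report


#: Per-sample QC thresholds of the study design (percent scale).
STUDY_QC_THRESHOLDS: dict[str, QCThresholds] = {
    "glucose-6h": QCThresholds(2000, 0.2),
    "glucose-12h": QCThresholds(2000, 0.2),
    "mix-glucose-maltose": QCThresholds(2000, 0.2),
    "lag-1h": QCThresholds(1500, 0.5),
    "lag-3h": QCThresholds(1500, 1.5),
}
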
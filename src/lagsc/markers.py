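"""Marker-panel classification of cells into subpopulations.

Cells growing on maltose express maltose-utilization genes (MAL transporters
and maltases, the isomaltase IMA1) and the glucose-repressed HXK1, which
glucose-grown cells do not. A cell is called positive when its summed raw UMI
count over the panel reaches ``min_transcripts`` (default 2). The rule runs
on raw counts — it is a transcript-count rule, so normalization never enters.

An alternative ``per_gene`` mode calls a cell positive when any single panel
gene alone reaches the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .counts_io import CountMatrix
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

#: Maltose-growth marker genes used by the study's mixed-sample control.
MALTOSE_MARKER_GENES = ("MAL11", "MAL12", "MAL31", "MAL32", "IMA1", "HXK1")


@dataclass
class MarkerPanel:
    """A set of marker genes plus the transcript-count decision rule."""

    gene_ids: tuple[str, ...] = MALTOSE_MARKER_GENES
    min_transcripts: int = 2
    positive_label: str = "maltose"
    negative_label: str = "glucose"
    mode: str = "summed"  # "summed" or "per_gene"

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        if not self.gene_ids:
            raise ConfigurationError("marker panel must contain at least one gene")
        if self.min_transcripts < 1:
            raise ConfigurationError("min_transcripts must be >= 1")
        if self.positive_label == self.negative_label:
            raise ConfigurationError("positive and negative labels must differ")
        if self.mode not in ("summed", "per_gene"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


@dataclass
class CellLabeling:
    """Barcode -> label mapping covering every cell of the source matrix."""

    labels: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, barcode: str) -> str:
        return self.labels[barcode]

    def group(self, label: str) -> list[str]:
        return [b for b, l in self.labels.items() if l == label]

    def as_array(self, barcodes: list[str]) -> np.ndarray:
        return np.array([self.labels[b] for b in barcodes])


def classify_by_markers(cm: CountMatrix, panel: MarkerPanel) -> CellLabeling:
    """Label each cell positive/negative by its raw panel transcript count."""
    present = [g for g in panel.gene_ids if g in cm.gene_ids]
    missing = [g for g in panel.gene_ids if g not in cm.gene_ids]
    if not present:
        raise ConfigurationError("no marker panel gene present in the count matrix")
    if missing:
        logger.warning("panel genes absent from matrix (contribute 0): %s", missing)
    rows = np.array([cm.gene_index(g) for g in present])
    panel_counts = cm.counts[rows, :]
    if panel.mode == "summed":
        positive = panel_counts.sum(axis=0) >= panel.min_transcripts
    else:
        positive = (panel_counts >= panel.min_transcripts).any(axis=0)
    labels = {
        bc: (panel.positive_label if pos else panel.negative_label)
        for bc, pos in zip(cm.barcodes, positive)
    }
    return CellLabeling(labels)
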
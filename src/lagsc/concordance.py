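"""Pseudobulk vs bulk RNA-seq concordance.

Summing UMI counts over all cells of a sample mimics a bulk measurement;
plotting that sum against fpkm from a matched bulk experiment (both log10
after adding a pseudo-count of 0.1) gives a scatter whose squared Pearson
correlation quantifies agreement between the platforms. Genes detected in
bulk but not in single-cell are excluded from the headline fit (they reflect
platform dropout rather than disagreement over shared signal); genes
detected only in single-cell are kept.

"Detected" means a strictly positive raw value on that axis. Genes detected
on neither axis carry no information and are dropped before the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .counts_io import BulkProfile, CountMatrix
from .exceptions import InsufficientDataError, UndefinedCorrelationError


@dataclass
class ConcordanceResult:
    """Summary of a pseudobulk/bulk comparison.

    ``r_squared`` is the headline number, computed with the bulk-only
    exclusion rule; ``r_squared_all`` includes every detected gene for
    comparison. ``per_gene`` holds the full transformed table.
    """

    r_squared: float
    r_squared_all: float
    n_common_detected: int
    n_sc_only: int
    n_bulk_only: int
    pseudo_count: float
    log_base: float
    exclusion_rule: str
    per_gene: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "r_squared_all": self.r_squared_all,
            "n_common_detected": self.n_common_detected,
            "n_sc_only": self.n_sc_only,
            "n_bulk_only": self.n_bulk_only,
            "pseudo_count": self.pseudo_count,
            "log_base": self.log_base,
            "exclusion_rule": self.exclusion_rule,
        }


def pseudobulk(cm: CountMatrix) -> pd.Series:
    """Per-gene total UMI count across all cells, indexed by gene id."""
    return pd.Series(cm.counts.sum(axis=1), index=cm.gene_ids, name="sc_total")


def _log_transform(v: np.ndarray, pseudo_count: float, base: float) -> np.ndarray:
    return np.log(v + pseudo_count) / np.log(base)


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance on one axis")
    r, _ = scipy.stats.pearsonr(x, y)
    return float(r * r)


def concordance_r2(
    sc_totals: pd.Series,
    bulk: BulkProfile,
    pseudo_count: float = 0.1,
    log_base: float = 10.0,
) -> ConcordanceResult:
    """Squared Pearson correlation of log pseudobulk vs log fpkm.

    ``sc_totals`` must be indexed by gene id (as from :func:`pseudobulk`).
    Gene universes are joined by exact id over the union; a gene absent from
    one table counts as 0 on that axis.
    """
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    sc = sc_totals.astype(float)
    bk = bulk.as_series().astype(float)
    universe = sc.index.union(bk.index, sort=False)
    sc = sc.reindex(universe, fill_value=0.0)
    bk = bk.reindex(universe, fill_value=0.0)

    sc_det = sc.to_numpy() > 0
    bk_det = bk.to_numpy() > 0
    table = pd.DataFrame(
        {
            "sc_total": sc.to_numpy(),
            "fpkm": bk.to_numpy(),
            "log_sc": _log_transform(sc.to_numpy(), pseudo_count, log_base),
            "log_fpkm": _log_transform(bk.to_numpy(), pseudo_count, log_base),
        },
        index=universe,
    )
    table["detection"] = np.select(
        [sc_det & bk_det, sc_det & ~bk_det, ~sc_det & bk_det],
        ["both", "sc_only", "bulk_only"],
        default="neither",
    )
    # headline fit: everything detected somewhere, minus the bulk-only set
    table["included"] = sc_det
    included = table[table["included"]]
    detected_any = table[table["detection"] != "neither"]
    if len(included) < 3:
        raise InsufficientDataError(
            f"only {len(included)} genes in the included set (need >= 3)"
        )
    r2 = _pearson_r2(included["log_sc"].to_numpy(), included["log_fpkm"].to_numpy())
    r2_all = _pearson_r2(
        detected_any["log_sc"].to_numpy(), detected_any["log_fpkm"].to_numpy()
    )
    return ConcordanceResult(
        r_squared=r2,
        r_squared_all=r2_all,
        n_common_detected=int((table["detection"] == "both").sum()),
        n_sc_only=int((table["detection"] == "sc_only").sum()),
        n_bulk_only=int((table["detection"] == "bulk_only").sum()),
        pseudo_count=float(pseudo_count),
        log_base=float(log_base),
        exclusion_rule="exclude_bulk_only",
        per_gene=table,
    )
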
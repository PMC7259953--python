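"""Lag-time relatedness: do sister cells behave more alike than strangers?

After a carbon-source shift, single founder cells trapped in a microfluidic
chamber have divided into micro-colonies of genealogically related cells, and
each cell's lag time (hours until it resumes division) is recorded, with
right-censoring for cells that never resume within the observation window.

The statistic compares absolute pairwise lag-time differences within
micro-colonies against differences across the whole population. Two variants:

``pairs_two_sample`` (default)
    One-sided Mann-Whitney U testing that within-colony pair differences are
    stochastically smaller than cross-colony pair differences.
``colony_means_one_sample``
    One-sided Wilcoxon signed-rank of per-colony mean pairwise differences
    against the population mean pairwise difference (the literal
    dots-versus-red-line reading of the scatter presentation).

Pair differences sharing a cell are not independent; the reported p-value is
flagged accordingly in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .diffexpr import rank_sum_test
from .exceptions import InsufficientDataError


@dataclass
class ColonyLagTable:
    """Colony-grouped single-cell lag times with right-censoring flags."""

    data: pd.DataFrame  # columns colony_id, cell_id, lag_time, resumed
    observation_window: float = 24.0

    def __post_init__(self) -> None:
        required = {"colony_id", "cell_id", "lag_time", "resumed"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.observation_window <= 0:
            raise ValueError("observation_window must be positive")
        if self.data["cell_id"].duplicated().any():
            raise ValueError("cell ids must be unique")
        if (self.data["lag_time"] < 0).any():
            raise ValueError("lag times must be non-negative")
        resumed = self.data["resumed"].astype(bool)
        if (self.data.loc[resumed, "lag_time"] > self.observation_window + 1e-9).any():
            raise ValueError("resumed cells must have lag_time <= observation_window")

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @classmethod
    def from_tsv(cls, path, observation_window: float = 24.0) -> "ColonyLagTable":
        df = pd.read_csv(path, sep="\t")
        df["resumed"] = df["resumed"].astype(bool)
        return cls(df, observation_window)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class PairwiseDiffs:
    within: np.ndarray
    between: np.ndarray
    colony_means: dict[str, float]
    population_mean: float


@dataclass
class LagComparisonResult:
    within_pair_diffs: np.ndarray
    between_pair_diffs: np.ndarray
    colony_mean_diffs: dict[str, float]
    population_mean_pairwise_diff: float
    statistic: float
    p_value: float
    method: str
    censoring: str
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "censoring": self.censoring,
            "n_within_pairs": int(len(self.within_pair_diffs)),
            "n_between_pairs": int(len(self.between_pair_diffs)),
            "population_mean_pairwise_diff": self.population_mean_pairwise_diff,
            "colony_mean_diffs": {k: float(v) for k, v in self.colony_mean_diffs.items()},
            **self.metadata,
        }


def _eligible(table: ColonyLagTable, censoring: str) -> pd.DataFrame:
    df = table.data.copy()
    df["resumed"] = df["resumed"].astype(bool)
    if censoring == "drop_censored":
        return df[df["resumed"]].reset_index(drop=True)
    if censoring == "window_max":
        df.loc[~df["resumed"], "lag_time"] = table.observation_window
        return df.reset_index(drop=True)
    raise ValueError(f"unknown censoring mode {censoring!r}")


def pairwise_lag_diffs(
    table: ColonyLagTable, censoring: str = "drop_censored"
) -> PairwiseDiffs:
    """Within-/cross-colony absolute lag differences over all unordered pairs.

    ``colony_means`` covers colonies with at least two eligible cells;
    ``population_mean`` averages over every unordered pair (within and
    between combined).
    """
    df = _eligible(table, censoring)
    n = len(df)
    counts = df["colony_id"].value_counts()
    if (counts >= 2).sum() < 2:
        raise InsufficientDataError(
            "need >= 2 colonies with >= 2 eligible cells each"
        )
    lags = df["lag_time"].to_numpy(dtype=float)
    colonies = df["colony_id"].to_numpy()
    iu, ju = np.triu_indices(n, k=1)
    diffs = np.abs(lags[iu] - lags[ju])
    same = colonies[iu] == colonies[ju]
    within = diffs[same]
    between = diffs[~same]
    colony_means: dict[str, float] = {}
    for colony in counts[counts >= 2].index:
        mask = same & (colonies[iu] == colony)
        colony_means[str(colony)] = float(diffs[mask].mean())
    return PairwiseDiffs(
        within=within,
        between=between,
        colony_means=colony_means,
        population_mean=float(diffs.mean()),
    )


def relatedness_test(
    table: ColonyLagTable,
    method: str = "pairs_two_sample",
    censoring: str = "drop_censored",
) -> LagComparisonResult:
    """Test that related cells have more similar lag times than the population."""
    d = pairwise_lag_diffs(table, censoring)
    if method == "pairs_two_sample":
        stat, p = rank_sum_test(d.within, d.between, alternative="less")
    elif method == "colony_means_one_sample":
        deltas = np.array(list(d.colony_means.values())) - d.population_mean
        nonzero = deltas[deltas != 0]
        if nonzero.size == 0:
            stat, p = 0.0, 1.0
        else:
            res = scipy.stats.wilcoxon(deltas, alternative="less", zero_method="wilcox")
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return LagComparisonResult(
        within_pair_diffs=d.within,
        between_pair_diffs=d.between,
        colony_mean_diffs=d.colony_means,
        population_mean_pairwise_diff=d.population_mean,
        statistic=float(stat),
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        method=method,
        censoring=censoring,
        metadata={"note": "pair differences share cells and are not independent"},
    )
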
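"""Two-group differential expression by Wilcoxon rank-sum test.

The per-gene test is a Mann-Whitney U with mid-rank tie handling: exact
p-values by enumeration over all rank assignments when the pooled sample is
small (n1 + n2 <= 12) and tie-free, otherwise a normal approximation with tie
correction and continuity correction. Multiple testing is controlled by
Benjamini-Hochberg over the tested genes; a gene is called significant when
its adjusted p-value passes the FDR threshold AND its absolute log2 fold
change passes the minimum.

Fold changes are computed on de-logged normalized means,
``log2((mean_a + fc_pseudo) / (mean_b + fc_pseudo))`` with means taken over
``expm1`` of the log-normalized values, so the fold change lives on the
depth-normalized count scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .markers import CellLabeling
from .normalize import NormalizedMatrix

#: pooled-sample size at or below which tie-free p-values are exact
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class DEParams:
    """Thresholds and knobs for a two-group comparison."""

    fdr_threshold: float = 0.05
    min_abs_log2fc: float = 0.25
    fc_pseudo: float = 0.01
    min_expressing_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be non-negative")
        if self.fc_pseudo <= 0:
            raise ValueError("fc_pseudo must be positive")
        if not 0 <= self.min_expressing_fraction <= 1:
            raise ValueError("min_expressing_fraction must be in [0, 1]")


def _exact_u_tails(n1: int, n2: int, u_obs: float) -> tuple[float, float]:
    """(P(U <= u_obs), P(U >= u_obs)) by enumeration over rank assignments.

    Assumes no ties, so ranks are the integers 1..n1+n2 and U takes integer
    values; enumerates all C(n1+n2, n1) assignments of ranks to group one.
    """
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2
    total = 0
    le = 0
    ge = 0
    for combo in combinations(range(1, n + 1), n1):
        u = sum(combo) - offset
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    return le / total, ge / total


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test of two samples.

    Returns ``(U, p)`` where U is the statistic for ``x`` (number of (x, y)
    pairs with x > y, counting ties as 1/2). ``alternative`` is one of
    ``two-sided``, ``less`` (x stochastically smaller) or ``greater``.

    Exact p by enumeration when ``len(x) + len(y) <= 12`` with no ties;
    otherwise normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n <= EXACT_ENUMERATION_LIMIT and not has_ties:
        p_le, p_ge = _exact_u_tails(n1, n2, u)
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "less":
            p = p_le
        else:
            p = p_ge
        return u, p

    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return u, 1.0
    sd = np.sqrt(var)
    if alternative == "two-sided":
        z = max(0.0, abs(u - mu) - 0.5) / sd
        p = min(1.0, 2.0 * scipy.stats.norm.sf(z))
    elif alternative == "less":
        z = (u - mu + 0.5) / sd
        p = float(scipy.stats.norm.cdf(z))
    else:
        z = (u - mu - 0.5) / sd
        p = float(scipy.stats.norm.sf(z))
    return u, p


def differential_expression(
    nm: NormalizedMatrix,
    labels: CellLabeling,
    group_a: str,
    group_b: str,
    params: DEParams | None = None,
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two labeled cell groups.

    Genes are pre-filtered to those expressed (raw count > 0) in at least
    ``min_expressing_fraction`` of cells in one group or the other; only
    tested genes appear in the output and enter the BH adjustment.

    Returns a DataFrame indexed by gene id with columns mean_a, mean_b,
    log2fc, pct_a, pct_b, p_value, p_adjusted, significant, direction.
    """
    if params is None:
        params = DEParams()
    label_arr = labels.as_array(nm.barcodes)
    for g in (group_a, group_b):
        if g not in label_arr:
            raise KeyError(f"no cells labeled {g!r}")
    a_idx = np.flatnonzero(label_arr == group_a)
    b_idx = np.flatnonzero(label_arr == group_b)

    counts = nm.source.counts
    expr = np.expm1(nm.values)
    pct_a = (counts[:, a_idx] > 0).mean(axis=1)
    pct_b = (counts[:, b_idx] > 0).mean(axis=1)
    tested = (pct_a >= params.min_expressing_fraction) | (
        pct_b >= params.min_expressing_fraction
    )
    tested_idx = np.flatnonzero(tested)

    mean_a = expr[np.ix_(tested_idx, a_idx)].mean(axis=1)
    mean_b = expr[np.ix_(tested_idx, b_idx)].mean(axis=1)
    log2fc = np.log2((mean_a + params.fc_pseudo) / (mean_b + params.fc_pseudo))

    pvals = np.empty(tested_idx.size)
    for row, gi in enumerate(tested_idx):
        _, pvals[row] = rank_sum_test(nm.values[gi, a_idx], nm.values[gi, b_idx])

    if tested_idx.size:
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        p_adj = pvals
    significant = (p_adj <= params.fdr_threshold) & (
        np.abs(log2fc) >= params.min_abs_log2fc
    )
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "pct_a": pct_a[tested_idx],
            "pct_b": pct_b[tested_idx],
            "p_value": pvals,
            "p_adjusted": p_adj,
            "significant": significant,
            "direction": direction,
        },
        index=pd.Index([nm.gene_ids[i] for i in tested_idx], name="gene_id"),
    )
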
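"""Rank-sum test against enumeration oracles; DE table gates and BH."""

import itertools

import numpy as np
import pytest
import scipy.stats

from lagsc import CellLabeling, CountMatrix, DEParams, differential_expression, log_normalize, rank_sum_test
from lagsc.synthdata import de_null_config, generate_counts


def enumeration_oracle(x, y, alternative="two-sided"):
    """Exact Mann-Whitney p by brute force over all rank assignments.

    Independent of the implementation: recomputes U for every way of
    assigning the pooled observations' ranks to group one.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.array(us)
    p_le = (us <= u_obs + 1e-9).mean()
    p_ge = (us >= u_obs - 1e-9).mean()
    if alternative == "two-sided":
        return min(1.0, 2 * min(p_le, p_ge))
    return p_le if alternative == "less" else p_ge


class TestRankSum:
    def test_identical_groups_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_example(self):
        # all of x below all of y: one tail 1/C(6,3) = 1/20, doubled
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(1, 3), (2, 2), (3, 4), (4, 4), (5, 5), (2, 8)])
    @pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
    def test_exact_p_equals_enumeration_oracle(self, n1, n2, alternative, rng):
        for _ in range(10):
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            x, y = vals[:n1], vals[n1:]
            _, p = rank_sum_test(x, y, alternative)
            assert p == pytest.approx(enumeration_oracle(x, y, alternative), abs=1e-12)

    def test_large_sample_matches_scipy_normal_approximation(self, rng):
        """Independent cross-check of the tie-corrected normal path."""
        x = rng.integers(0, 6, 40).astype(float)
        y = rng.integers(0, 7, 55).astype(float)
        _, p = rank_sum_test(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


def _null_setup(seed, n_effect=0):
    cfg = de_null_config(seed=seed, n_effect_genes=n_effect)
    cm, truth = generate_counts(cfg)
    nm = log_normalize(cm)
    labels = CellLabeling(dict(zip(cm.barcodes, truth.cells["population"])))
    return cfg, nm, labels


class TestDifferentialExpression:
    def test_null_gene_fraction_near_alpha(self):
        """Exchangeable groups: ~5% of raw p-values fall below 0.05."""
        _, nm, labels = _null_setup(seed=101)
        table = differential_expression(nm, labels, "groupA", "groupB")
        frac = (table["p_value"] <= 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_significance_requires_both_gates(self):
        """adjusted p and fold change must BOTH pass."""
        _, nm, labels = _null_setup(seed=102, n_effect=200)
        table = differential_expression(nm, labels, "groupB", "groupA")
        sig = table[table["significant"]]
        assert (sig["p_adjusted"] <= 0.05).all()
        assert (sig["log2fc"].abs() >= 0.25).all()
        not_sig = table[~table["significant"]]
        assert (
            (not_sig["p_adjusted"] > 0.05) | (not_sig["log2fc"].abs() < 0.25)
        ).all()

    def test_bh_adjustment_properties(self):
        _, nm, labels = _null_setup(seed=103, n_effect=100)
        table = differential_expression(nm, labels, "groupA", "groupB")
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()
        # BH equals an independent step-up recomputation
        p = table["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, p[i] * m / (rank_pos + 1))
            adj[i] = running
        assert np.allclose(table["p_adjusted"].to_numpy(), adj)

    def test_label_swap_negates_log2fc_and_keeps_p(self):
        _, nm, labels = _null_setup(seed=104, n_effect=50)
        ab = differential_expression(nm, labels, "groupA", "groupB")
        ba = differential_expression(nm, labels, "groupB", "groupA")
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["p_value"], ba["p_value"])

    def test_prefilter_by_expressing_fraction(self, rng):
        counts = rng.integers(0, 5, size=(4, 40))
        counts[0, :] = 0
        counts[0, 0] = 1  # expressed in 1/20 cells of group A only
        cm = CountMatrix(counts, [f"g{i}" for i in range(4)],
                         [f"b{i}" for i in range(40)])
        nm = log_normalize(cm)
        labels = CellLabeling({b: ("A" if i < 20 else "B")
                               for i, b in enumerate(cm.barcodes)})
        table = differential_expression(nm, labels, "A", "B",
                                        DEParams(min_expressing_fraction=0.1))
        assert "g0" not in table.index

    def test_unknown_group_label_rejected(self):
        _, nm, labels = _null_setup(seed=105)
        with pytest.raises(KeyError):
            differential_expression(nm, labels, "groupA", "nonexistent")
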
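"""Generator contracts: determinism, invariants, moments, droplet structure."""

import numpy as np
import pytest
import scipy.stats

from lagsc import (
    BulkProfile,
    ColonySimConfig,
    CountMatrix,
    concordance_r2,
    generate_bulk_pair,
    generate_colony_lags,
    generate_counts,
    pairwise_lag_diffs,
    pseudobulk,
)
from lagsc.exceptions import ConfigurationError
from lagsc.synthdata import (
    Population,
    SynthConfig,
    mix_glucose_maltose_config,
    three_population_config,
)


class TestGenerateCounts:
    def test_same_seed_identical_matrices(self):
        a, _ = generate_counts(mix_glucose_maltose_config(seed=5))
        b, _ = generate_counts(mix_glucose_maltose_config(seed=5))
        assert np.array_equal(a.counts, b.counts)

    def test_different_seed_differs(self):
        a, _ = generate_counts(mix_glucose_maltose_config(seed=5))
        b, _ = generate_counts(mix_glucose_maltose_config(seed=6))
        assert not np.array_equal(a.counts, b.counts)

    def test_output_satisfies_count_matrix_invariants(self):
        cm, truth = generate_counts(three_population_config(seed=2))
        assert (cm.counts >= 0).all()
        assert np.issubdtype(cm.counts.dtype, np.integer)
        assert len(set(cm.barcodes)) == cm.n_cells
        assert len(truth.cells) == cm.n_cells

    def test_seed_isolation_across_subsystems(self):
        """Appending empty droplets does not scramble the filled-cell draws."""
        cfg_c = mix_glucose_maltose_config(seed=8)
        cfg_d = mix_glucose_maltose_config(seed=8, n_empty_droplets=50)
        c, _ = generate_counts(cfg_c)
        d, _ = generate_counts(cfg_d)
        assert np.array_equal(c.counts, d.counts[:, : c.n_cells])

    def test_sample_mean_tracks_program_rate(self):
        """No ambient/doublets/modules: per-gene mean ~ rate x mean library."""
        n_genes, n_cells = 100, 1500
        program = np.linspace(0.5, 2.0, n_genes)
        cfg = SynthConfig(
            gene_ids=[f"g{i}" for i in range(n_genes)],
            populations=[Population("only", n_cells, program)],
            ambient_fraction=0.0,
            doublet_rate=0.0,
            damaged_cell_fraction=0.0,
            seed=31,
        )
        cm, _ = generate_counts(cfg)
        norm = program / program.sum()
        mean_library = np.exp(cfg.library_size_log_mean + cfg.library_size_log_sd**2 / 2)
        expected = norm * mean_library
        observed = cm.counts.mean(axis=1)
        se = cm.counts.std(axis=1) / np.sqrt(n_cells)
        within = np.abs(observed - expected) <= 3 * se
        assert within.mean() >= 0.95  # a few 3-SE misses are expected by chance

    def test_filled_and_empty_droplet_umi_ranges(self):
        cm, truth = generate_counts(mix_glucose_maltose_config(seed=4, n_empty_droplets=200))
        totals = cm.counts.sum(axis=0)
        empty = truth.cells["is_empty"].to_numpy()
        filled_median = np.median(totals[~empty])
        empty_median = np.median(totals[empty])
        assert 1000 <= filled_median <= 10000
        assert 50 <= empty_median <= 200
        assert filled_median / empty_median > 5

    def test_doublets_flagged_and_heavier(self):
        cfg = mix_glucose_maltose_config(seed=12)
        cfg.doublet_rate = 0.2
        cm, truth = generate_counts(cfg)
        totals = cm.counts.sum(axis=0)
        dbl = truth.cells["is_doublet"].to_numpy()
        assert dbl.sum() == round(0.2 * cm.n_cells)
        assert np.median(totals[dbl]) > np.median(totals[~dbl])

    def test_damaged_cells_have_elevated_mito(self):
        cm, truth = generate_counts(mix_glucose_maltose_config(seed=13))
        mito_frac = cm.counts[cm.mito_flags].sum(axis=0) / cm.counts.sum(axis=0)
        dmg = truth.cells["is_damaged"].to_numpy()
        assert dmg.any()
        assert mito_frac[dmg].mean() > 5 * mito_frac[~dmg].mean()

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(gene_ids=["a"], populations=[
                Population("p", 5, np.ones(1), marker_genes=("missing",))])


class TestGenerateColonyLags:
    def test_no_variance_all_lags_equal(self):
        cfg = ColonySimConfig(seed=1, colony_sd=0.0, cell_sd=0.0,
                              nonresume_probability=0.0, lag_mean=9.0)
        t, _ = generate_colony_lags(cfg)
        assert (t.data["lag_time"] == 9.0).all()
        assert t.data["resumed"].all()

    def test_all_nonresuming_leaves_no_eligible_cells(self):
        cfg = ColonySimConfig(seed=1, nonresume_probability=1.0)
        t, _ = generate_colony_lags(cfg)
        assert not t.data["resumed"].any()

    def test_null_within_between_distributions_match(self):
        """sigma_b = 0: within and between pair diffs agree in law (small KS)."""
        cfg = ColonySimConfig(seed=17, colony_sd=0.0, cell_sd=1.0, n_colonies=300,
                              nonresume_probability=0.0)
        t, _ = generate_colony_lags(cfg)
        d = pairwise_lag_diffs(t)
        ks = scipy.stats.ks_2samp(d.within, d.between).statistic
        assert ks < 0.08

    def test_median_colony_size_three(self):
        cfg = ColonySimConfig(seed=23, n_colonies=200)
        t, _ = generate_colony_lags(cfg)
        sizes = t.data.groupby("colony_id").size()
        assert np.median(sizes) == 3

    def test_target_cell_count_honored(self):
        t, _ = generate_colony_lags(ColonySimConfig(seed=2, n_cells_target=133))
        assert len(t.data) == 133


class TestGenerateBulkPair:
    def test_zero_noise_gives_perfect_concordance(self):
        cm, _ = generate_counts(mix_glucose_maltose_config(seed=3))
        bulk = generate_bulk_pair(cm, noise_sd=0.0)
        res = concordance_r2(pseudobulk(cm), bulk)
        assert res.r_squared == pytest.approx(1.0)

    def test_bulk_side_zeroing_counted_as_sc_only(self):
        cm, _ = generate_counts(mix_glucose_maltose_config(seed=3))
        pb = pseudobulk(cm)
        detected = [g for g in cm.gene_ids if pb[g] > 0][:5]
        bulk = generate_bulk_pair(cm, noise_sd=0.0, zero_bulk_genes=tuple(detected))
        res = concordance_r2(pb, bulk)
        assert res.n_sc_only == 5

    def test_r2_decreases_with_noise(self):
        cm, _ = generate_counts(mix_glucose_maltose_config(seed=3))
        pb = pseudobulk(cm)
        r2 = [concordance_r2(pb, generate_bulk_pair(cm, noise_sd=sd, seed=41)).r_squared
              for sd in (0.0, 0.3, 1.0)]
        assert r2[0] > r2[1] > r2[2]
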
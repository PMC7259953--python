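# Methods

## Scope and data model

`lagsc` analyzes gene × cell UMI count matrices from droplet scRNA-seq of
budding yeast, together with two companion inputs: a bulk RNA-seq profile
(gene, fpkm) for platform concordance, and a micro-colony lag-time table
(colony id, cell id, lag time in hours, resumed-growth flag) from time-lapse
microscopy. Counts are held genes × cells everywhere; readers transpose as
needed. Mitochondrial genes are recognized by an id-prefix rule (default
`Q0`, the systematic naming of the yeast mitochondrial genome; configurable)
because count matrices do not carry chromosome annotations. Gene ids are
matched case-sensitively and gene universes are never reconciled implicitly:
joins (e.g. concordance) are by exact id over the union, with absences
counting as zero.

Upstream read processing (base calling, alignment, UMI deduplication,
barcode/cell calling) is out of scope; the pipeline starts at the count
matrix, as produced by the platform vendor's counting tool.

## Quality control

Cells are removed when detected genes (> `max_genes_detected`; doublet
proxy) or mitochondrial percentage (> `max_mito_pct`; dying-cell proxy)
strictly exceed their caps — cells exactly at a cap are kept, matching the
"maximum was set to X" convention. Study-style per-sample caps ship as
`STUDY_QC_THRESHOLDS` (2000 genes / 0.2% for glucose-grown and mixed
samples; 1500 / 0.5% and 1500 / 1.5% for the two lag samples). The mito cap
is interpreted on the percent scale (0.2 means 0.2%); because the written
convention is ambiguous, `mito_pct_is_fraction=True` switches the same
number to fraction scale. No lower bound on genes or UMIs is applied —
empty-droplet removal is a barcode-calling concern, emulated only in the
generator. QC is idempotent and monotone in both thresholds (property
tests).

## Normalization

`log_normalize` computes `ln(1 + s·x/N)` per cell with scale factor
`s = 10⁴` (the common default of the normalization this mirrors; the source
analyses do not state parameters, so it is exposed in config). Zero-total
cells are kept as zero columns; dropping cells is QC's job. Two invariants
pin the transform: `Σ_g expm1(v_gc) = s` for every non-empty cell, and
within-cell rank order of counts is preserved.

## Differential expression

The per-gene test is a two-sided Mann–Whitney U with mid-rank tie handling,
written in-package: exact p by enumeration over all C(n₁+n₂, n₁) rank
assignments when the pooled sample is ≤ 12 and tie-free, otherwise a normal
approximation with tie correction and a 0.5 continuity correction. The exact
path is validated against an independent enumeration oracle in the tests,
and the asymptotic path against an established implementation.

Genes enter testing when expressed (raw count > 0) in ≥ 10% of cells of at
least one group (set `min_expressing_fraction=0` to test everything). Fold
change is `log2((m_a + 0.01)/(m_b + 0.01))` on de-logged normalized means,
so it lives on the depth-normalized count scale. Multiplicity is handled by
Benjamini–Hochberg over tested genes — an FDR criterion, matching the
thresholding convention reproduced here (FDR ≤ 0.05 AND |log2FC| ≥ 0.25).
Swapping group labels negates fold changes and leaves p-values unchanged
(tested).

## Co-expression networks

Order of operations: (1) UMI filter (total raw UMIs ≥ 10 across the
population); (2) pairwise Pearson r on normalized values across cells, with
p from `t = r√((n−2)/(1−r²))`; (3) Bonferroni over all unordered tested
pairs — the most conservative natural reading, since the family is not
stated in the source; (4) edges need `|r| ≥ 0.1` and adjusted `p ≤ 0.05`;
(5) degree pruning at ≥ 7 significant partners, with degrees frozen on the
pre-prune gene set (`single_pass`, default) or recomputed to a fixed point
(`iterative`) — the original order of operations is not recoverable, so
both are available; (6) the identity diagonal is zeroed; (7) retained
correlation rows are clustered into `n_modules` (default 6) by agglomerative
clustering on Euclidean distances (average linkage default), with k-means as
an alternative because the published description names both. Zero-variance
genes get r = 0, p = 1 and can never form edges. Module labels are
arbitrary; evaluation uses best-match Jaccard and ARI.

## Cell clustering

Cells are embedded by PCA of gene-standardized normalized expression
(center + unit variance, zero-variance guard) and partitioned by k-means
(k-means++, best of `n_init` seeded restarts). The graph-based clustering
with a tuned resolution knob used in the original analysis is deliberately
replaced by an explicit k: the scientific claim being tested — a known
number of transcriptional subgroups is recoverable — does not depend on the
partitioner, and explicit k removes an unreproducible tuning step. This is a
documented simplification, not a re-implementation. An optional top-N
variance gene restriction exists but is off by default: on synthetic data
per-gene variance tracks expression level rather than signal, and the
restriction measurably hurts recovery.

## Concordance

Pseudobulk = per-gene UMI sums across cells. Both axes are transformed as
`log10(x + 0.1)`; the same pseudo-count is applied to fpkm for symmetry
(its bulk-side value is not stated in the source). "Detected" means
strictly positive raw value. Genes detected in bulk only are excluded from
the headline R² (platform dropout, not disagreement); single-cell-only
genes are included; genes detected on neither axis are dropped as
uninformative. R² is the squared Pearson correlation — identical to the
regression R² with free intercept — and the all-detected-genes variant is
reported alongside, with the rule recorded in the result.

## Loading arithmetic

Expected recovered cells = Σᵢ wᵢ·cᵢ / d with concentrations cᵢ (cells/mL),
mixing weights wᵢ, and recovery divisor d = 100 — the consistent
concentration→expected mapping of the loading table (2.15×10⁵ → 2150, and
(606 + 1320)·0.5 = 963 for the 50-50 mix). The divisor is a parameter rather
than being derived from loading volume × capture rate, because only the
outcome mapping is documented. Integer reports round half away from zero.
A planning inverse (`required_concentration`) is provided.

## Lag-time relatedness

Eligibility under censoring: `drop_censored` (default) uses only resumed
cells — lag times exist only for resumers; `window_max` assigns the
observation window (24 h) as a lower-bound lag to non-resumers. The default
test compares the within-colony and cross-colony sets of absolute pairwise
lag differences by a one-sided Mann–Whitney U; the alternative
`colony_means_one_sample` applies a one-sided Wilcoxon signed-rank to
per-colony mean differences against the population mean pairwise
difference. Pair differences share cells and are therefore not independent;
the result metadata flags this. Empirically the pairs test is slightly
conservative under the null (rejection ≈ 0.037 at α = 0.05 with 133 cells
and median colony size 3), and the package's calibration checks measure the
rate over 2500 simulated replicates so the Monte-Carlo standard error
(~0.004) is small against the calibration band. Exact identities —
|within| + |between| = C(n, 2), and the population mean being the weighted
combination of the two set means — are asserted in tests.

## Synthetic data generator

What it emulates, per droplet run:

- **Populations.** Each population has a relative expression program
  (normalized internally); cells get rates `program × module latents ×
  library size`.
- **Library sizes.** Lognormal, median ≈ 1500 UMIs, log-sd 0.45 — matching
  observed per-cell medians near 900–1300 and filled-droplet totals of
  roughly 1,000–10,000.
- **Counting noise.** Negative binomial with size (dispersion) 2 —
  overdispersion beyond Poisson is the droplet-data norm; exposed.
- **Planted modules.** A shared per-cell lognormal multiplier (sd 1.0)
  applied to a gene subset induces positive within-module Pearson
  correlation (median |r| ≈ 0.4 in the discovery preset) — exactly the
  structure the network stage must detect. The sd is calibrated so the
  median within-module |r| clears 0.3.
- **Ambient mRNA.** Every filled droplet's rates are mixed with fraction
  0.01 of a cell-count-weighted population-average profile ("soup" from
  prematurely lysed cells). Empty droplets, when requested, carry pure soup
  with Poisson(100)-scale totals. The 1% share for filled droplets follows
  from capture competition: a cell's 20,000–60,000 mRNA molecules dwarf the
  ambient molecules that give empties their ~100 UMIs.
- **Doublets.** 1.5% of barcodes receive the summed counts of a second
  sampled cell (typical of runs recovering one-to-two thousand cells);
  truth records host and donor populations.
- **Damaged cells.** 5% of cells have mitochondrial rates boosted 20×;
  with a healthy mito share of ~0.05% of the transcriptome this puts
  damaged cells far above the 0.2% QC cap and healthy cells safely below.
- **Colony lags.** `lag = lag_mean + b_colony + ε_cell` (Normal effects,
  truncated at 0), colony sizes {2: 0.25, 3: 0.5, 4: 0.25} (median 3),
  defaults `lag_mean` 10 h, window 24 h, non-resumption probability 0.15 —
  the lag regime of glucose→maltose shifts (5 to > 20 h, some cells never
  resuming).

Subsystem draws use isolated seeded streams (library sizes, module latents,
counts, doublets, empties, damaged flags, colonies, bulk noise), so adding
empty droplets, say, does not scramble the filled-cell counts.

Presets encode the planted-truth study conditions used by the calibration
checks: `mix_glucose_maltose_config` (343 + 343 cells, 300 genes, six
maltose markers at ~0.15% of the maltose transcriptome each),
`three_population_config` (3 × 200 cells, 60-gene blocks at fold e — unit
natural-log separation), `coexpr_discovery_config` (500 cells, two 15-gene
modules + 100 background + 3 near-silent genes among 130), and
`de_null_config` (2 × 200 cells, 2000 genes, ~3 UMIs/gene; planted effects
are 1.5× half up / half down so composition stays balanced — planting all
effects in one direction makes every other gene weakly but truly DE through
depth renormalization and is a known compositional artifact, not a test
failure).

What the generator does **not** model: sequencing-saturation and barcode
errors, gene length or GC effects, cell-cycle structure, batch effects,
zero inflation beyond NB sampling, and real biological co-regulation beyond
single shared latents. Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration under the stated statistical
structure, not performance on any particular real dataset.

## Problem sizes and numerical choices

Calibration suites run at: 2000 genes × 400 cells (DE), 130 genes × 500
cells (co-expression), 600 cells (clustering), 686 cells (markers), 133
cells / ~44 colonies × 2500 null + 300 power replicates (lag relatedness).
Exact rank-sum enumeration is limited to pooled n ≤ 12 (≤ 924
combinations). Bonferroni uses min(1, p·n_pairs). Correlations are clipped
to [−1, 1]; zero-variance guards return r = 0, p = 1. k-means and PCA are
deterministic given the seed (full SVD solver, seeded restarts). BH is the
standard step-up; adjusted p never falls below raw p. Degenerate inputs
(empty matrices, zero-total cells, empty networks) return empty results
rather than raising, except where a statistic is genuinely undefined
(fewer than 3 cells for correlation p-values, fewer than 3 genes or a
zero-variance axis for concordance, fewer than 2 usable colonies for the
relatedness test).

## Known limitations

- The relatedness p-value treats dependent pairs as independent (flagged in
  output); a cell-level permutation test would be the rigorous alternative.
- Bonferroni over all gene pairs is very conservative for dense networks.
- The marker rule's default reading sums transcripts across the panel; a
  per-gene threshold mode exists because the published sentence admits both
  readings.
- Expected-cell arithmetic encodes the documented outcome mapping, not a
  mechanistic droplet-occupancy model.
- Fold-change pseudo-counts (0.01) and the fpkm pseudo-count (0.1) follow
  convention where sources are silent; both are parameters.
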
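"""Synthetic droplet scRNA-seq and micro-colony lag-time generators.

The count generator emulates the data-generating situation of a droplet run
on budding yeast: one or more cell populations with distinct expression
programs and marker genes; planted co-expression modules driven by a shared
per-cell lognormal latent activity; lognormal library-size variation (filled
droplets carrying on the order of 1,000-10,000 UMIs); negative-binomial
counting noise (droplet data are overdispersed relative to Poisson); ambient
mRNA contamination from a population-average "soup" (empty droplets carry
~100 UMIs; in filled droplets the cell's own 20,000-60,000 mRNA molecules
dominate the capture competition, keeping the ambient share near 1%);
doublets formed by summing two sampled cells; and a damaged-cell fraction
with boosted mitochondrial content.

The colony generator emulates the microfluidic lag-time experiment: founder
cells grow into micro-colonies (sizes 2-4, median 3), and each cell's lag is
``lag_mean + b_colony + eps_cell`` (normal colony and cell effects, truncated
at 0), with independent right-censoring for cells that never resume growth
within the observation window.

Every generator consumes an isolated seeded stream per subsystem, so changing
one configuration field does not scramble unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import BulkProfile, CountMatrix
from .exceptions import ConfigurationError
from .lineage import ColonyLagTable
from .markers import MALTOSE_MARKER_GENES

# fixed spawn keys for seed-isolated subsystem streams
_STREAMS = {
    "library": 0,
    "modules": 1,
    "counts": 2,
    "doublets": 3,
    "empties": 4,
    "damaged": 5,
    "colonies": 6,
    "bulk": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class Population:
    """One cell population: name, size and per-gene relative expression rates."""

    name: str
    n_cells: int
    program: np.ndarray  # per-gene relative rates, positive where expressed
    marker_genes: tuple[str, ...] = ()


@dataclass
class Module:
    """A planted co-expression module: gene subset plus latent strength."""

    gene_ids: tuple[str, ...]
    latent_sd: float = 1.0


@dataclass
class SynthConfig:
    """Full configuration for one synthetic droplet run.

    Defaults encode the study-like regime: lognormal libraries with median
    ~1,500 UMIs, NB dispersion 2, 1% ambient contamination, 1.5% doublets,
    a 5% damaged-cell fraction with 20x mitochondrial boost, and empty
    droplets with Poisson(100) ambient counts when requested.
    """

    gene_ids: list[str]
    populations: list[Population]
    modules: list[Module] = field(default_factory=list)
    library_size_log_mean: float = float(np.log(1500.0))
    library_size_log_sd: float = 0.45
    dispersion: float = 2.0
    ambient_fraction: float = 0.01
    doublet_rate: float = 0.015
    n_empty_droplets: int = 0
    empty_umi_mean: float = 100.0
    mito_gene_ids: tuple[str, ...] = ()
    damaged_cell_fraction: float = 0.05
    damaged_mito_boost: float = 20.0
    sample_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        universe = set(self.gene_ids)
        if len(universe) != len(self.gene_ids):
            raise ConfigurationError("duplicate gene ids")
        for pop in self.populations:
            pop.program = np.asarray(pop.program, dtype=float)
            if pop.program.shape != (len(self.gene_ids),):
                raise ConfigurationError(
                    f"population {pop.name!r} program length mismatch"
                )
            if (pop.program < 0).any():
                raise ConfigurationError("program rates must be non-negative")
            if not set(pop.marker_genes) <= universe:
                raise ConfigurationError("marker genes outside gene universe")
        for mod in self.modules:
            if not set(mod.gene_ids) <= universe:
                raise ConfigurationError("module genes outside gene universe")
            if mod.latent_sd < 0:
                raise ConfigurationError("latent_sd must be non-negative")
        if not set(self.mito_gene_ids) <= universe:
            raise ConfigurationError("mito genes outside gene universe")
        if not 0 <= self.ambient_fraction < 1:
            raise ConfigurationError("ambient_fraction must be in [0, 1)")
        if not 0 <= self.doublet_rate < 1:
            raise ConfigurationError("doublet_rate must be in [0, 1)")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")


@dataclass
class SynthTruth:
    """Ground truth accompanying a generated matrix."""

    cells: pd.DataFrame  # index barcode: population, is_doublet, partner, is_damaged, is_empty
    gene_modules: pd.Series  # gene -> module index (NaN outside modules)
    module_gene_sets: dict[str, set[str]]

    @property
    def filled_barcodes(self) -> list[str]:
        return list(self.cells.index[~self.cells["is_empty"]])


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative binomial with mean/size parametrization, elementwise."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def generate_counts(cfg: SynthConfig) -> tuple[CountMatrix, SynthTruth]:
    """Simulate one droplet run. Deterministic given ``cfg.seed``."""
    n_genes = len(cfg.gene_ids)
    gene_index = {g: i for i, g in enumerate(cfg.gene_ids)}
    mito_idx = np.array([gene_index[g] for g in cfg.mito_gene_ids], dtype=int)

    pop_norms = []
    for pop in cfg.populations:
        total = pop.program.sum()
        if total <= 0:
            raise ConfigurationError(f"population {pop.name!r} has all-zero program")
        pop_norms.append(pop.program / total)
    n_cells_total = sum(p.n_cells for p in cfg.populations)
    weights = np.array([p.n_cells for p in cfg.populations], dtype=float)
    ambient_profile = np.average(np.stack(pop_norms), axis=0, weights=weights)

    lib_rng = _rng(cfg.seed, "library")
    mod_rng = _rng(cfg.seed, "modules")
    cnt_rng = _rng(cfg.seed, "counts")
    dmg_rng = _rng(cfg.seed, "damaged")

    libraries = np.exp(
        lib_rng.normal(cfg.library_size_log_mean, cfg.library_size_log_sd, n_cells_total)
    )
    damaged = dmg_rng.random(n_cells_total) < cfg.damaged_cell_fraction

    # per-cell per-gene rates
    rates = np.zeros((n_genes, n_cells_total))
    pop_of_cell = np.empty(n_cells_total, dtype=object)
    start = 0
    for pop, norm in zip(cfg.populations, pop_norms):
        stop = start + pop.n_cells
        rates[:, start:stop] = norm[:, np.newaxis]
        pop_of_cell[start:stop] = pop.name
        start = stop

    # planted module activity: shared lognormal multiplier per (cell, module)
    for mod in cfg.modules:
        idx = np.array([gene_index[g] for g in mod.gene_ids], dtype=int)
        latent = np.exp(mod_rng.normal(0.0, mod.latent_sd, n_cells_total))
        rates[idx, :] *= latent[np.newaxis, :]

    # damaged cells leak mitochondrial transcripts
    if mito_idx.size and cfg.damaged_mito_boost != 1.0:
        boost = np.where(damaged, cfg.damaged_mito_boost, 1.0)
        rates[np.ix_(mito_idx, np.arange(n_cells_total))] *= boost[np.newaxis, :]

    # ambient soup mixes into every filled droplet
    own = (1.0 - cfg.ambient_fraction) * rates
    soup = cfg.ambient_fraction * ambient_profile[:, np.newaxis]
    mean_matrix = (own + soup) * libraries[np.newaxis, :]

    counts = _nb_sample(cnt_rng, mean_matrix, cfg.dispersion)

    # doublets: chosen barcodes receive the counts of a second sampled cell
    dbl_rng = _rng(cfg.seed, "doublets")
    n_doublets = int(round(cfg.doublet_rate * n_cells_total))
    is_doublet = np.zeros(n_cells_total, dtype=bool)
    partner_pop = np.array([""] * n_cells_total, dtype=object)
    if n_doublets:
        hosts = dbl_rng.choice(n_cells_total, size=n_doublets, replace=False)
        for h in hosts:
            donor = int(dbl_rng.integers(n_cells_total))
            while donor == h:
                donor = int(dbl_rng.integers(n_cells_total))
            counts[:, h] += counts[:, donor]
            is_doublet[h] = True
            partner_pop[h] = pop_of_cell[donor]

    # empty droplets: pure ambient, Poisson totals around empty_umi_mean
    emp_rng = _rng(cfg.seed, "empties")
    n_empty = cfg.n_empty_droplets
    if n_empty:
        empty_counts = emp_rng.poisson(
            cfg.empty_umi_mean * ambient_profile[:, np.newaxis], (n_genes, n_empty)
        )
        counts = np.concatenate([counts, empty_counts], axis=1)

    barcodes = [f"BC{i:06d}" for i in range(counts.shape[1])]
    mito_flags = np.zeros(n_genes, dtype=bool)
    mito_flags[mito_idx] = True
    cm = CountMatrix(counts, list(cfg.gene_ids), barcodes, cfg.sample_label, mito_flags)

    cells = pd.DataFrame(
        {
            "population": list(pop_of_cell) + ["ambient"] * n_empty,
            "is_doublet": list(is_doublet) + [False] * n_empty,
            "partner_population": list(partner_pop) + [""] * n_empty,
            "is_damaged": list(damaged) + [False] * n_empty,
            "is_empty": [False] * n_cells_total + [True] * n_empty,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    gene_modules = pd.Series(np.nan, index=cfg.gene_ids, name="module")
    module_sets: dict[str, set[str]] = {}
    for mi, mod in enumerate(cfg.modules, start=1):
        gene_modules.loc[list(mod.gene_ids)] = mi
        module_sets[f"module_{mi}"] = set(mod.gene_ids)
    return cm, SynthTruth(cells, gene_modules, module_sets)


@dataclass
class ColonySimConfig:
    """Configuration for the micro-colony lag-time simulator."""

    n_colonies: int = 44
    colony_size_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.25, 3: 0.5, 4: 0.25}
    )
    lag_mean: float = 10.0
    colony_sd: float = 2.0
    cell_sd: float = 1.0
    nonresume_probability: float = 0.15
    observation_window: float = 24.0
    n_cells_target: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.colony_sd < 0 or self.cell_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if not 0 <= self.nonresume_probability <= 1:
            raise ConfigurationError("nonresume_probability must be in [0, 1]")
        total = sum(self.colony_size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("colony size probabilities must sum to 1")


def generate_colony_lags(cfg: ColonySimConfig) -> tuple[ColonyLagTable, dict]:
    """Simulate micro-colony lag times. Deterministic given ``cfg.seed``.

    When ``n_cells_target`` is set, colonies are drawn until the target cell
    count is reached (the last colony is truncated, never below 2 cells).
    """
    rng = _rng(cfg.seed, "colonies")
    sizes = np.array(sorted(cfg.colony_size_distribution))
    probs = np.array([cfg.colony_size_distribution[s] for s in sizes])
    rows = []
    n_cells = 0
    colony_i = 0
    while True:
        if cfg.n_cells_target is None:
            if colony_i >= cfg.n_colonies:
                break
        elif n_cells >= cfg.n_cells_target:
            break
        size = int(rng.choice(sizes, p=probs))
        if cfg.n_cells_target is not None:
            size = min(size, max(2, cfg.n_cells_target - n_cells))
        b = rng.normal(0.0, cfg.colony_sd)
        for j in range(size):
            eps = rng.normal(0.0, cfg.cell_sd)
            lag = max(0.0, cfg.lag_mean + b + eps)
            resumed = rng.random() >= cfg.nonresume_probability
            if resumed:
                lag = min(lag, cfg.observation_window)
            else:
                lag = cfg.observation_window
            rows.append((f"colony{colony_i:04d}", f"cell{colony_i:04d}_{j}", lag, resumed))
        n_cells += size
        colony_i += 1
    df = pd.DataFrame(rows, columns=["colony_id", "cell_id", "lag_time", "resumed"])
    table = ColonyLagTable(df, observation_window=cfg.observation_window)
    return table, {"colony_sd": cfg.colony_sd, "cell_sd": cfg.cell_sd}


def generate_bulk_pair(
    cm: CountMatrix,
    noise_sd: float = 0.0,
    zero_bulk_genes: tuple[str, ...] = (),
    seed: int = 0,
    scale: float = 1e6,
) -> BulkProfile:
    """A matched bulk profile: pseudobulk totals with lognormal noise.

    ``zero_bulk_genes`` are zeroed on the bulk side only, exercising the
    single-cell-only detection bookkeeping of the concordance report.
    """
    rng = _rng(seed, "bulk")
    totals = cm.counts.sum(axis=1).astype(float)
    grand = totals.sum()
    fpkm = scale * totals / max(grand, 1.0)
    if noise_sd > 0:
        fpkm = fpkm * np.exp(rng.normal(0.0, noise_sd, fpkm.shape))
    for g in zero_bulk_genes:
        fpkm[cm.gene_index(g)] = 0.0
    return BulkProfile(list(cm.gene_ids), fpkm)


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

def mix_glucose_maltose_config(
    seed: int = 0,
    n_cells_per_population: int = 343,
    n_genes: int = 300,
    n_empty_droplets: int = 0,
) -> SynthConfig:
    """Two-population 50-50 mix: glucose-grown vs maltose-grown cells.

    Maltose cells express the six maltose-growth markers (~0.15% of the
    transcriptome each); glucose cells repress them completely, so any marker
    UMI in a glucose cell comes from ambient contamination or a doublet.
    Ten mitochondrial genes (Q0-prefixed ids) carry ~0.05% of the transcriptome
    in healthy cells, comfortably below the 0.2% QC cap that damaged cells
    (20x mito boost) exceed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    n_mito = 10
    markers = list(MALTOSE_MARKER_GENES)
    n_background = n_genes - n_mito - len(markers)
    gene_ids = (
        [f"YAL{i:03d}W" for i in range(n_background)]
        + markers
        + [f"Q{i:04d}" for i in range(45, 45 + n_mito)]
    )
    mito_ids = tuple(gene_ids[-n_mito:])

    # lognormal background expression, shared backbone with population tilts
    backbone = np.exp(rng.normal(0.0, 1.0, n_background))
    glucose = np.concatenate([backbone, np.zeros(len(markers)), np.full(n_mito, 1e-4)])
    maltose_bg = backbone * np.exp(rng.normal(0.0, 0.3, n_background))
    marker_rates = np.full(len(markers), 0.0015) * backbone.sum()
    maltose = np.concatenate([maltose_bg, marker_rates, np.full(n_mito, 1e-4)])
    # scale mito to ~0.1% of each transcriptome
    for prog in (glucose, maltose):
        prog[-n_mito:] = 0.0005 * prog[:-n_mito].sum() / n_mito

    return SynthConfig(
        gene_ids=gene_ids,
        populations=[
            Population("glucose", n_cells_per_population, glucose),
            Population("maltose", n_cells_per_population, maltose,
                       marker_genes=tuple(markers)),
        ],
        mito_gene_ids=mito_ids,
        n_empty_droplets=n_empty_droplets,
        sample_label="mix-glucose-maltose",
        seed=seed,
    )


def three_population_config(
    seed: int = 0,
    n_cells_per_population: int = 200,
    n_genes: int = 300,
    n_marker_block: int = 60,
    fold: float = float(np.e),
) -> SynthConfig:
    """Three populations, each upregulating its own block of genes by ``fold``.

    Mirrors the situation of one baseline state plus two diverged states:
    60 genes per block at unit log-fold (e ~ 2.72x) mean separation, i.e.
    comfortably past a 2x separation on >= 50 genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(98,)))
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    base = np.exp(rng.normal(0.0, 0.8, n_genes))
    progs = []
    for p in range(3):
        prog = base.copy()
        if p > 0:
            lo = (p - 1) * n_marker_block
            prog[lo : lo + n_marker_block] *= fold
        progs.append(prog)
    return SynthConfig(
        gene_ids=gene_ids,
        populations=[
            Population(f"pop{p + 1}", n_cells_per_population, progs[p])
            for p in range(3)
        ],
        sample_label="three-population",
        seed=seed,
    )


def coexpr_discovery_config(
    seed: int = 0,
    n_cells: int = 500,
    n_module_genes: int = 15,
    n_background: int = 100,
    latent_sd: float = 1.0,
    n_silent: int = 3,
) -> SynthConfig:
    """One population with two planted co-expression modules.

    130 genes by default: 2 x 15 module genes, 100 background genes and a few
    near-silent genes expected to fall under the 10-UMI population total.
    Module genes sit at ~0.2% of the transcriptome each so that the shared
    lognormal latent (sd 1.0, calibrated so the median within-module |r| clears
    0.3) yields strong within-module correlation while
    the compositional footprint on background genes stays small.
    """
    n_genes = 2 * n_module_genes + n_background + n_silent
    gene_ids = (
        [f"MODA{i:03d}" for i in range(n_module_genes)]
        + [f"MODB{i:03d}" for i in range(n_module_genes)]
        + [f"BG{i:03d}" for i in range(n_background)]
        + [f"SILENT{i:02d}" for i in range(n_silent)]
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))
    background = np.exp(rng.normal(0.0, 0.5, n_background))
    background *= 0.94 / background.sum()
    module_rate = 0.002
    silent_rate = 1e-5
    program = np.concatenate(
        [
            np.full(2 * n_module_genes, module_rate),
            background,
            np.full(n_silent, silent_rate),
        ]
    )
    mod_a = tuple(gene_ids[:n_module_genes])
    mod_b = tuple(gene_ids[n_module_genes : 2 * n_module_genes])
    return SynthConfig(
        gene_ids=gene_ids,
        populations=[Population("glucose", n_cells, program)],
        modules=[Module(mod_a, latent_sd), Module(mod_b, latent_sd)],
        sample_label="glucose-12h",
        seed=seed,
    )


def de_null_config(
    seed: int = 0,
    n_genes: int = 2000,
    n_cells: int = 400,
    n_effect_genes: int = 0,
    fold: float = 1.5,
) -> SynthConfig:
    """One (or two) populations of equal size for DE calibration.

    With ``n_effect_genes == 0`` the two halves of the cells are exchangeable
    (a pure null). Otherwise the first ``n_effect_genes`` genes carry a
    ``fold`` effect in the second population, half up- and half
    down-regulated so the planted effects barely perturb the transcriptome
    composition of the remaining genes. Libraries around 6,000 UMIs give a
    per-gene mean of ~3 at 2,000 genes.
    """
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    base = np.ones(n_genes)
    pops = []
    if n_effect_genes == 0:
        pops.append(Population("groupA", n_cells // 2, base))
        pops.append(Population("groupB", n_cells - n_cells // 2, base.copy()))
    else:
        alt = base.copy()
        half = n_effect_genes // 2
        alt[:half] *= fold
        alt[half:n_effect_genes] /= fold
        pops.append(Population("groupA", n_cells // 2, base))
        pops.append(Population("groupB", n_cells - n_cells // 2, alt))
    return SynthConfig(
        gene_ids=gene_ids,
        populations=pops,
        library_size_log_mean=float(np.log(6000.0)),
        library_size_log_sd=0.3,
        ambient_fraction=0.0,
        doublet_rate=0.0,
        damaged_cell_fraction=0.0,
        sample_label="de-calibration",
        seed=seed,
    )
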
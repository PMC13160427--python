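"""Factorial synthetic scRNA-seq generator with ground-truth factors.

Generates negative-binomially distributed counts from a factorial design:
every cell belongs to one level of each categorical factor (batch,
experimental conditions, cell type), and each factor level perturbs a gene-wise
log-mean profile. Batch effects act multiplicatively on all genes;
biological conditions shift a subset of genes; each cell type has its own
marker program. The default configuration reproduces a published benchmark
layout: 2 batches x 2 conditions x 2 conditions x 16 cell types,
500 genes, 660 cells per type with one rare 200-cell type.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionDataset, FactorSpec, LabelTable

__all__ = ["SimFactor", "SimConfig", "SimOutput", "default_config", "tiny_config",
           "simulate", "summarize"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimFactor:
    """One generative factor: its levels and per-level effect on gene means."""

    name: str
    n_levels: int
    effect_gene_fraction: float = 0.1
    effect_logfc_sd: float = 1.0
    level_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("factors need >=2 levels")
        if not 0.0 < self.effect_gene_fraction <= 1.0:
            raise ValueError("effect_gene_fraction must be in (0, 1]")
        if self.effect_logfc_sd < 0:
            raise ValueError("effect_logfc_sd must be non-negative")
        if self.level_names is not None and len(self.level_names) != self.n_levels:
            raise ValueError("level_names length mismatch")

    @property
    def levels(self) -> list[str]:
        if self.level_names is not None:
            return list(self.level_names)
        return [f"{self.name}{i}" for i in range(self.n_levels)]


@dataclass(frozen=True)
class SimConfig:
    """Full description of a factorial simulation run."""

    n_genes: int
    factors: tuple[SimFactor, ...]
    cell_type_counts: tuple[int, ...]
    batch_factor_name: str
    depth_mean: float = 2000.0
    nb_dispersion: float = 1.0
    seed: int = 0
    cell_type_factor_name: str = "cell_type"
    marker_gene_fraction: float = 0.2
    marker_logfc_sd: float = 1.0
    residual_dim: int = 10

    def __post_init__(self):
        names = [f.name for f in self.factors]
        if self.batch_factor_name not in names:
            raise ValueError("batch_factor_name must name one of the factors")
        if self.cell_type_factor_name not in names:
            raise ValueError("cell_type_factor_name must name one of the factors")
        ct = self.cell_type_factor
        if len(self.cell_type_counts) != ct.n_levels:
            raise ValueError("cell_type_counts length must equal cell_type levels")
        if any(c < 1 for c in self.cell_type_counts):
            raise ValueError("all cell_type_counts must be >=1")
        if self.n_genes < 1 or self.depth_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("invalid size/depth/dispersion")

    @property
    def cell_type_factor(self) -> SimFactor:
        return next(f for f in self.factors if f.name == self.cell_type_factor_name)

    @property
    def subset_factors(self) -> list[SimFactor]:
        """All non-cell-type factors; their level product defines the subsets."""
        return [f for f in self.factors if f.name != self.cell_type_factor_name]

    @property
    def n_cells(self) -> int:
        return int(sum(self.cell_type_counts))

    def factor_spec(self) -> FactorSpec:
        return FactorSpec.build(
            [(f.name, f.levels) for f in self.factors], residual_dim=self.residual_dim
        )


@dataclass
class SimOutput:
    """Simulated counts plus full ground truth."""

    dataset: ExpressionDataset
    truth: LabelTable
    spec: FactorSpec
    gene_effects: pd.DataFrame  # rows: baseline + (factor, level) log-FCs; cols: genes
    config: SimConfig = field(repr=False, default=None)


def default_config(seed: int = 0) -> SimConfig:
    """The benchmark-replica configuration.

    500 genes; factors batch(2) x condition1(2: Ctrl/Stim) x
    condition2(2: Healthy/Severe) x cell_type(16); 660 cells per cell type
    except the rare type 2 with 200 cells (10 100 cells total, eight
    batch-by-condition subsets).
    """
    counts = [660] * 16
    counts[2] = 200
    return SimConfig(
        n_genes=500,
        factors=(
            SimFactor("batch", 2, effect_gene_fraction=1.0, effect_logfc_sd=0.3,
                      level_names=("batch1", "batch2")),
            SimFactor("condition1", 2, effect_gene_fraction=0.1, effect_logfc_sd=1.0,
                      level_names=("Ctrl", "Stim")),
            SimFactor("condition2", 2, effect_gene_fraction=0.1, effect_logfc_sd=1.0,
                      level_names=("Healthy", "Severe")),
            SimFactor("cell_type", 16,
                      level_names=tuple(f"type{i}" for i in range(16))),
        ),
        cell_type_counts=tuple(counts),
        batch_factor_name="batch",
        seed=seed,
    )


def tiny_config(seed: int = 0) -> SimConfig:
    """A reduced configuration for quick runs: 2000 cells, 200 genes, 8 types."""
    return SimConfig(
        n_genes=200,
        factors=(
            SimFactor("batch", 2, effect_gene_fraction=1.0, effect_logfc_sd=0.3,
                      level_names=("batch1", "batch2")),
            SimFactor("condition1", 2, effect_gene_fraction=0.1, effect_logfc_sd=1.0,
                      level_names=("Ctrl", "Stim")),
            SimFactor("condition2", 2, effect_gene_fraction=0.1, effect_logfc_sd=1.0,
                      level_names=("Healthy", "Severe")),
            SimFactor("cell_type", 8,
                      level_names=tuple(f"type{i}" for i in range(8))),
        ),
        cell_type_counts=(250,) * 8,
        batch_factor_name="batch",
        depth_mean=1500.0,
        seed=seed,
    )


def _allocate(count: int, n_subsets: int) -> list[int]:
    """Split a per-type cell count deterministically and near-evenly."""
    base, rem = divmod(count, n_subsets)
    return [base + (1 if s < rem else 0) for s in range(n_subsets)]


def simulate(config: SimConfig) -> SimOutput:
    """Draw a full factorial dataset; bit-reproducible given the config seed."""
    rng = np.random.default_rng(config.seed)
    d = config.n_genes
    ct = config.cell_type_factor
    subset_factors = config.subset_factors
    subsets = list(itertools.product(*(range(f.n_levels) for f in subset_factors)))
    n_subsets = len(subsets)

    # gene-wise baseline log-mean (relative expression; depth sets the scale)
    baseline = rng.normal(0.0, 0.5, size=d)

    # cell-type marker programs: log-shifts on a random marker subset per type
    n_markers = max(1, round(config.marker_gene_fraction * d))
    type_lfc = np.zeros((ct.n_levels, d))
    for t in range(ct.n_levels):
        genes = rng.choice(d, size=n_markers, replace=False)
        type_lfc[t, genes] = rng.normal(0.0, config.marker_logfc_sd, size=n_markers)

    # per-level effects of each non-cell-type factor (batch hits all genes)
    factor_lfc: dict[str, np.ndarray] = {}
    for f in subset_factors:
        n_eff = max(1, round(f.effect_gene_fraction * d))
        lfc = np.zeros((f.n_levels, d))
        for lev in range(f.n_levels):
            genes = rng.choice(d, size=n_eff, replace=False)
            lfc[lev, genes] = rng.normal(0.0, f.effect_logfc_sd, size=n_eff)
        factor_lfc[f.name] = lfc

    rows, labels_rows = [], []
    factor_order = list(config.factors)
    for t in range(ct.n_levels):
        alloc = _allocate(config.cell_type_counts[t], n_subsets)
        if 0 in alloc:
            log.info("cell type %d has fewer cells than subsets; some subsets empty", t)
        for s, (combo, n_cells) in enumerate(zip(subsets, alloc)):
            if n_cells == 0:
                continue
            lm = baseline + type_lfc[t]
            for f, lev in zip(subset_factors, combo):
                lm = lm + factor_lfc[f.name][lev]
            rel = np.exp(lm)
            mu = config.depth_mean * rel / rel.sum()
            lam = rng.gamma(shape=config.nb_dispersion,
                            scale=mu / config.nb_dispersion,
                            size=(n_cells, d))
            counts = rng.poisson(lam)
            rows.append(counts)
            lab = np.empty(len(factor_order), dtype=np.int64)
            for jf, f in enumerate(factor_order):
                if f.name == ct.name:
                    lab[jf] = t
                else:
                    lab[jf] = combo[subset_factors.index(f)]
            labels_rows.append(np.tile(lab, (n_cells, 1)))

    matrix = np.vstack(rows).astype(np.float64)
    labels = np.vstack(labels_rows)
    n = matrix.shape[0]
    dataset = ExpressionDataset(
        matrix,
        [f"cell_{i:05d}" for i in range(n)],
        [f"gene_{g:04d}" for g in range(d)],
        "raw_counts",
    )
    spec = config.factor_spec()
    truth = LabelTable.full(labels, spec.n_categories)

    eff_rows, eff_index = [baseline], [("baseline", "-")]
    for t in range(ct.n_levels):
        eff_rows.append(type_lfc[t])
        eff_index.append((ct.name, ct.levels[t]))
    for f in subset_factors:
        for lev in range(f.n_levels):
            eff_rows.append(factor_lfc[f.name][lev])
            eff_index.append((f.name, f.levels[lev]))
    gene_effects = pd.DataFrame(
        np.vstack(eff_rows),
        index=pd.MultiIndex.from_tuples(eff_index, names=["factor", "level"]),
        columns=dataset.gene_ids,
    )
    return SimOutput(dataset=dataset, truth=truth, spec=spec,
                     gene_effects=gene_effects, config=config)


def summarize(sim: SimOutput) -> pd.DataFrame:
    """Per-subset x per-cell-type cell counts; column sums give per-type totals."""
    config = sim.config
    ct = config.cell_type_factor
    subset_factors = config.subset_factors
    names = sim.spec.names
    ct_col = names.index(ct.name)
    sub_cols = [names.index(f.name) for f in subset_factors]
    subsets = list(itertools.product(*(range(f.n_levels) for f in subset_factors)))
    labels = sim.truth.labels
    table = np.zeros((len(subsets), ct.n_levels), dtype=np.int64)
    sub_lut = {combo: s for s, combo in enumerate(subsets)}
    for i in range(labels.shape[0]):
        combo = tuple(labels[i, c] for c in sub_cols)
        table[sub_lut[combo], labels[i, ct_col]] += 1
    idx = [
        "/".join(f.levels[lev] for f, lev in zip(subset_factors, combo))
        for combo in subsets
    ]
    return pd.DataFrame(table, index=pd.Index(idx, name="subset"), columns=ct.levels)
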
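"""Synthetic multi-batch, multi-condition scRNA-seq count generator.

The generator emulates the structure of the benchmark design used for
integration testing: three conditions (time points T1-T3) with two samples
each, six cell types of which three (c1-c3) are shared across all samples
and three (c4-c6) are each restricted to a single condition, plus additive
log-scale batch effects and planted condition-specific DE genes.

Counts are negative binomial with mean exp(baseline + type markers +
condition DE shift + per-(gene, batch) shift) and fixed dispersion alpha
(variance = mu + alpha * mu^2), sampled as a gamma-Poisson mixture. The
sample id doubles as the batch label. Ground truth (cell type, batch,
condition, per-condition DE gene sets) is returned alongside the counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import ExpressionDataset, Stage

__all__ = ["SimulationDesign", "GroundTruth", "simulate_dataset", "easy_benchmark", "default_design"]


@dataclass
class SimulationDesign:
    """Composition table and effect sizes for one simulated dataset.

    ``composition`` maps (condition, sample) -> {cell_type: count}. The
    default replicates the benchmark table: each sample holds 100 cells of
    each of five types, the condition-excluded type being absent (T1 lacks
    c4, T2 lacks c5, T3 lacks c6), for 3000 cells total over 4977 genes.
    """

    composition: dict[tuple[str, str], dict[str, int]]
    n_genes: int = 4977
    n_condition_de_genes: int = 30
    batch_effect_sd: float = 0.3
    condition_logfc: float = 1.5
    type_logfc: float = 2.0
    marker_fraction: float = 0.05
    base_logmean_loc: float = 0.0
    base_logmean_scale: float = 1.0
    nb_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.composition:
            raise ValueError("composition table is empty")
        for key, row in self.composition.items():
            if any(v < 0 for v in row.values()):
                raise ValueError(f"negative cell count in composition row {key}")
        conds = self.conditions
        if any(sum(1 for (c, _) in self.composition if c == cond) < 1 for cond in conds):
            raise ValueError("every condition needs at least one sample")

    @property
    def conditions(self) -> list[str]:
        return sorted({c for c, _ in self.composition})

    @property
    def samples(self) -> list[str]:
        return sorted({s for _, s in self.composition})

    @property
    def cell_types(self) -> list[str]:
        return sorted({t for row in self.composition.values() for t in row})

    @property
    def n_cells(self) -> int:
        return sum(v for row in self.composition.values() for v in row.values())


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    cell_type: np.ndarray
    batch: np.ndarray
    condition: np.ndarray
    de_genes: dict[str, list[str]]  # condition -> planted DE gene ids
    marker_genes: dict[str, list[str]]  # cell type -> marker gene ids

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "de_genes": self.de_genes,
            "marker_genes": self.marker_genes,
        }, indent=2))


def default_design(cells_per_type: int = 100, n_genes: int = 4977, **overrides) -> SimulationDesign:
    """The benchmark composition: 3 conditions x 2 samples, 6 cell types,
    each sample carrying ``cells_per_type`` cells of each non-excluded type."""
    conditions = ["T1", "T2", "T3"]
    excluded = {"T1": "c4", "T2": "c5", "T3": "c6"}
    types = ["c1", "c2", "c3", "c4", "c5", "c6"]
    composition: dict[tuple[str, str], dict[str, int]] = {}
    sample_no = 1
    for cond in conditions:
        for _ in range(2):
            composition[(cond, f"S{sample_no}")] = {
                t: (0 if t == excluded[cond] else cells_per_type) for t in types
            }
            sample_no += 1
    return SimulationDesign(composition=composition, n_genes=n_genes, **overrides)


def simulate_dataset(design: SimulationDesign) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset from the design. Deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    m = design.n_genes
    genes = [f"gene{i + 1:05d}" for i in range(m)]
    conditions = design.conditions
    samples = design.samples
    types = design.cell_types

    base = rng.normal(design.base_logmean_loc, design.base_logmean_scale, size=m)

    # disjoint gene blocks: per-type markers first, then per-condition DE sets
    perm = rng.permutation(m)
    n_marker = int(round(design.marker_fraction * m))
    needed = n_marker * len(types) + design.n_condition_de_genes * len(conditions)
    if needed > m:
        raise ValueError("not enough genes for disjoint marker and DE sets")
    cursor = 0
    type_effect = {t: np.zeros(m) for t in types}
    marker_genes: dict[str, list[str]] = {}
    for t in types:
        idx = perm[cursor : cursor + n_marker]
        cursor += n_marker
        type_effect[t][idx] = design.type_logfc
        marker_genes[t] = sorted(genes[i] for i in idx)
    cond_effect = {c: np.zeros(m) for c in conditions}
    de_genes: dict[str, list[str]] = {}
    for c in conditions:
        idx = perm[cursor : cursor + design.n_condition_de_genes]
        cursor += design.n_condition_de_genes
        cond_effect[c][idx] = design.condition_logfc
        de_genes[c] = sorted(genes[i] for i in idx)

    batch_shift = {s: rng.normal(0.0, design.batch_effect_sd, size=m) for s in samples}

    counts_blocks, cell_ids, cell_type, batch, condition = [], [], [], [], []
    r = 1.0 / design.nb_dispersion  # NB size: var = mu + alpha mu^2
    for (cond, sample) in sorted(design.composition):
        for t in types:
            n_ct = design.composition[(cond, sample)].get(t, 0)
            if n_ct == 0:
                continue
            mu = np.exp(base + type_effect[t] + cond_effect[cond] + batch_shift[sample])
            lam = rng.gamma(shape=r, scale=mu / r, size=(n_ct, m))
            counts_blocks.append(rng.poisson(lam))
            cell_ids.extend(f"{sample}_{t}_{i + 1:04d}" for i in range(n_ct))
            cell_type.extend([t] * n_ct)
            batch.extend([sample] * n_ct)
            condition.extend([cond] * n_ct)

    ds = ExpressionDataset(
        matrix=np.vstack(counts_blocks).astype(np.float64),
        gene_ids=genes,
        cell_ids=cell_ids,
        batch=np.asarray(batch),
        condition=np.asarray(condition),
        cell_type=np.asarray(cell_type),
        stage=Stage.raw,
    )
    truth = GroundTruth(
        cell_type=np.asarray(cell_type),
        batch=np.asarray(batch),
        condition=np.asarray(condition),
        de_genes=de_genes,
        marker_genes=marker_genes,
    )
    return ds, truth


def easy_benchmark(seed: int = 0) -> tuple[ExpressionDataset, GroundTruth]:
    """Small preset for fast end-to-end runs: 600 cells (20 per type per
    sample), 1000 genes, strong type and condition effects, moderate batch
    effects."""
    design = default_design(
        cells_per_type=20,
        n_genes=1000,
        n_condition_de_genes=30,
        batch_effect_sd=0.3,
        condition_logfc=2.0,
        type_logfc=2.5,
        marker_fraction=0.06,
        seed=seed,
    )
    return simulate_dataset(design)
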
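"""Dataset container, label encodings, I/O and the preprocessing pipeline.

The universal unit is :class:`ExpressionDataset`: a cell-by-gene matrix with
per-cell batch and condition labels (and optional cell-type labels for
evaluation). Preprocessing follows the standard recipe for integration
models: filter sparse cells and silent genes, library-size normalize to the
median total, log-transform, keep the top highly variable genes, and z-score
each gene so the reconstruction target has zero mean and unit variance.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "OneHot",
    "ExpressionDataset",
    "read_dataset",
    "write_dataset",
    "filter_cells_genes",
    "normalize_library_size",
    "log_select_hvg",
    "zscore_genes",
    "preprocess",
]

MIN_GENES_PER_CELL = 200


class Stage(enum.IntEnum):
    """Preprocessing stage; transitions only move forward."""

    raw = 0
    normalized = 1
    log = 2
    hvg = 3
    zscored = 4


@dataclass(frozen=True)
class OneHot:
    """Integer coding plus indicator matrix for a categorical label vector.

    Codes follow the lexicographic sort of the distinct level names, so the
    coding is stable across runs and across subsets that contain the same
    levels.
    """

    levels: tuple[str, ...]
    codes: np.ndarray  # (n,) int
    matrix: np.ndarray  # (n, k) float indicator

    @classmethod
    def from_labels(cls, labels: Sequence, levels: Sequence[str] | None = None) -> "OneHot":
        labels = np.asarray([str(x) for x in labels])
        if levels is None:
            levels = tuple(sorted(set(labels.tolist())))
        else:
            levels = tuple(levels)
            unknown = set(labels.tolist()) - set(levels)
            if unknown:
                raise ValueError(f"labels contain unseen levels: {sorted(unknown)}")
        index = {lev: i for i, lev in enumerate(levels)}
        codes = np.asarray([index[x] for x in labels], dtype=np.int64)
        matrix = np.zeros((len(labels), len(levels)), dtype=np.float64)
        matrix[np.arange(len(labels)), codes] = 1.0
        return cls(levels=levels, codes=codes, matrix=matrix)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class ExpressionDataset:
    """Cell x gene expression matrix with aligned per-cell annotations.

    ``matrix`` may be dense or CSR sparse up to the z-score step (z-scored
    data is dense by nature). Batch and condition levels are coded by
    lexicographic sort of their names.
    """

    matrix: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    batch: np.ndarray
    condition: np.ndarray
    cell_type: np.ndarray | None = None
    stage: Stage = Stage.raw

    def __post_init__(self) -> None:
        n, m = self.matrix.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.batch = np.asarray([str(x) for x in self.batch])
        self.condition = np.asarray([str(x) for x in self.condition])
        if self.cell_type is not None:
            self.cell_type = np.asarray([str(x) for x in self.cell_type])
        if len(self.gene_ids) != m:
            raise ValueError(f"gene_ids length {len(self.gene_ids)} != {m} columns")
        for name, vec in [("cell_ids", self.cell_ids), ("batch", self.batch), ("condition", self.condition)] + (
            [("cell_type", self.cell_type)] if self.cell_type is not None else []
        ):
            if len(vec) != n:
                raise ValueError(f"{name} length {len(vec)} != {n} rows")

    # -- basic properties -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def batch_onehot(self, levels: Sequence[str] | None = None) -> OneHot:
        return OneHot.from_labels(self.batch, levels)

    def condition_onehot(self, levels: Sequence[str] | None = None) -> OneHot:
        return OneHot.from_labels(self.condition, levels)

    def dense(self) -> np.ndarray:
        X = self.matrix
        return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)

    def subset_cells(self, index: np.ndarray) -> "ExpressionDataset":
        return replace(
            self,
            matrix=self.matrix[index],
            cell_ids=[self.cell_ids[i] for i in np.atleast_1d(index)]
            if index.dtype != bool
            else [c for c, keep in zip(self.cell_ids, index) if keep],
            batch=self.batch[index],
            condition=self.condition[index],
            cell_type=None if self.cell_type is None else self.cell_type[index],
        )

    # -- AnnData bridge ---------------------------------------------------
    def to_anndata(self) -> ad.AnnData:
        X = self.matrix
        adata = ad.AnnData(
            X=sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X, dtype=np.float64),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.obs["batch"] = pd.Categorical(self.batch)
        adata.obs["condition"] = pd.Categorical(self.condition)
        if self.cell_type is not None:
            adata.obs["cell_type"] = pd.Categorical(self.cell_type)
        adata.uns["stage"] = self.stage.name
        return adata

    @classmethod
    def from_anndata(
        cls,
        adata: ad.AnnData,
        batch_key: str = "batch",
        condition_key: str = "condition",
        celltype_key: str | None = "cell_type",
    ) -> "ExpressionDataset":
        for key in (batch_key, condition_key):
            if key not in adata.obs:
                raise KeyError(f"obs column '{key}' not found in AnnData object")
        cell_type = None
        if celltype_key is not None and celltype_key in adata.obs:
            cell_type = adata.obs[celltype_key].to_numpy()
        X = adata.X
        if not (sp.issparse(X) or np.issubdtype(np.asarray(X).dtype, np.number)):
            raise ValueError("expression matrix is not numeric")
        stage = Stage[adata.uns.get("stage", "raw")] if "stage" in adata.uns else Stage.raw
        return cls(
            matrix=X.copy() if sp.issparse(X) else np.asarray(X, dtype=np.float64).copy(),
            gene_ids=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            batch=adata.obs[batch_key].to_numpy(),
            condition=adata.obs[condition_key].to_numpy(),
            cell_type=cell_type,
            stage=stage,
        )


# -- readers / writers ----------------------------------------------------

def read_dataset(
    path: str | Path,
    format: str = "h5ad",
    batch_key: str = "batch",
    condition_key: str = "condition",
    celltype_key: str | None = "cell_type",
    metadata_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read an annotated expression matrix from h5ad, CSV or MTX.

    CSV expects a cells x genes matrix (first column = cell ids, header =
    gene ids) plus a metadata CSV keyed by cell id. MTX expects the usual
    triple ``matrix.mtx`` / ``genes.tsv`` / ``barcodes.tsv`` in a directory,
    plus a metadata CSV; the matrix is stored genes x cells as 10x does.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "h5ad":
        return ExpressionDataset.from_anndata(
            ad.read_h5ad(path), batch_key=batch_key, condition_key=condition_key, celltype_key=celltype_key
        )
    if format == "csv":
        frame = pd.read_csv(path, index_col=0)
        if not all(np.issubdtype(dt, np.number) for dt in frame.dtypes):
            raise ValueError("CSV expression matrix contains non-numeric columns")
        if metadata_path is None:
            raise ValueError("csv format requires metadata_path")
        meta = pd.read_csv(metadata_path, index_col=0).loc[frame.index]
        return _from_matrix_meta(frame.to_numpy(dtype=np.float64), list(frame.columns), list(frame.index.astype(str)),
                                 meta, batch_key, condition_key, celltype_key)
    if format == "mtx":
        from scipy.io import mmread

        mat = mmread(path / "matrix.mtx").tocsr().T.tocsr()  # stored genes x cells
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        if metadata_path is None:
            metadata_path = path / "metadata.csv"
        meta = pd.read_csv(metadata_path, index_col=0).loc[cells]
        return _from_matrix_meta(mat, genes, cells, meta, batch_key, condition_key, celltype_key)
    raise ValueError(f"unknown format '{format}'")


def _from_matrix_meta(matrix, genes, cells, meta, batch_key, condition_key, celltype_key):
    for key in (batch_key, condition_key):
        if key not in meta.columns:
            raise KeyError(f"metadata column '{key}' not found")
    cell_type = meta[celltype_key].to_numpy() if celltype_key is not None and celltype_key in meta.columns else None
    return ExpressionDataset(
        matrix=matrix,
        gene_ids=genes,
        cell_ids=cells,
        batch=meta[batch_key].to_numpy(),
        condition=meta[condition_key].to_numpy(),
        cell_type=cell_type,
    )


def write_dataset(ds: ExpressionDataset, path: str | Path) -> None:
    """Write the dataset as h5ad, recording the preprocessing stage."""
    ds.to_anndata().write_h5ad(Path(path))


# -- preprocessing ops -----------------------------------------------------

def filter_cells_genes(ds: ExpressionDataset, min_genes: int = MIN_GENES_PER_CELL) -> ExpressionDataset:
    """Remove cells expressing fewer than ``min_genes`` genes and genes
    expressed in zero cells.

    Both masks are computed on the raw matrix and applied in one sweep (no
    iterative re-filtering), which makes the operation reproducible and
    order-independent.
    """
    if ds.stage != Stage.raw:
        raise ValueError(f"filter expects stage=raw, got {ds.stage.name}")
    X = ds.matrix
    if sp.issparse(X):
        nz = X != 0
        genes_per_cell = np.asarray(nz.sum(axis=1)).ravel()
        cells_per_gene = np.asarray(nz.sum(axis=0)).ravel()
    else:
        nz = X != 0
        genes_per_cell = nz.sum(axis=1)
        cells_per_gene = nz.sum(axis=0)
    cell_mask = genes_per_cell >= min_genes
    gene_mask = cells_per_gene >= 1
    if not cell_mask.any():
        raise ValueError("all cells removed by the expressed-gene filter")
    out = ds.subset_cells(cell_mask)
    out.matrix = out.matrix[:, gene_mask] if not sp.issparse(out.matrix) else out.matrix[:, np.flatnonzero(gene_mask)]
    out.gene_ids = [g for g, keep in zip(ds.gene_ids, gene_mask) if keep]
    return out


def normalize_library_size(ds: ExpressionDataset) -> ExpressionDataset:
    """Divide each cell by its library size factor (total / median total)."""
    if ds.stage != Stage.raw:
        raise ValueError(f"normalize expects stage=raw, got {ds.stage.name}")
    X = ds.matrix
    totals = np.asarray(X.sum(axis=1)).ravel()
    median = float(np.median(totals))
    if median <= 0:
        raise ValueError("median total count is zero; cannot form size factors")
    factors = totals / median
    factors[factors == 0] = 1.0  # empty cells pass through unchanged
    if sp.issparse(X):
        out = sp.diags(1.0 / factors) @ X.tocsr()
    else:
        out = np.asarray(X, dtype=np.float64) / factors[:, None]
    res = replace(ds, matrix=out)
    res.stage = Stage.normalized
    return res


def log_select_hvg(ds: ExpressionDataset, n_hvg: int = 3000) -> ExpressionDataset:
    """log(1+x)-transform, then keep the top ``n_hvg`` highly variable genes.

    Genes are ranked by Seurat-flavor normalized dispersion; ties are broken
    by gene identifier order so the selection is deterministic.
    """
    if ds.stage != Stage.normalized:
        raise ValueError(f"hvg selection expects stage=normalized, got {ds.stage.name}")
    X = ds.matrix
    logX = X.copy()
    if sp.issparse(logX):
        logX = logX.tocsr()
        logX.data = np.log1p(logX.data)
    else:
        logX = np.log1p(np.asarray(logX, dtype=np.float64))
    n_keep = min(n_hvg, ds.n_genes)
    if n_keep == ds.n_genes:
        order = np.arange(ds.n_genes)
    else:
        adata = ad.AnnData(X=sp.csr_matrix(logX) if sp.issparse(logX) else logX)
        adata.var_names = ds.gene_ids
        sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_keep)
        disp = np.nan_to_num(adata.var["dispersions_norm"].to_numpy(dtype=np.float64), nan=-np.inf)
        # constant genes are never highly variable, whatever the binned
        # normalization says on small inputs
        if sp.issparse(logX):
            col_var = np.asarray(logX.multiply(logX).mean(axis=0)).ravel() - np.asarray(logX.mean(axis=0)).ravel() ** 2
        else:
            col_var = logX.var(axis=0)
        disp[col_var <= 1e-12] = -np.inf
        # descending dispersion, ties by gene id
        keys = sorted(range(ds.n_genes), key=lambda i: (-disp[i], ds.gene_ids[i]))
        order = np.sort(np.asarray(keys[:n_keep]))
    res = replace(ds, matrix=logX[:, order] if not sp.issparse(logX) else logX[:, order],
                  gene_ids=[ds.gene_ids[i] for i in order])
    res.stage = Stage.hvg
    return res


def zscore_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize each gene to zero mean, unit (population) variance.

    Zero-variance genes become all-zero columns (logged, not an error).
    Output is dense.
    """
    if ds.stage != Stage.hvg:
        raise ValueError(f"z-score expects stage=hvg, got {ds.stage.name}")
    X = ds.dense().astype(np.float64)
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population (1/n) convention
    flat = std == 0
    if flat.any():
        logger.info("z-score: %d zero-variance genes set to 0", int(flat.sum()))
    std_safe = np.where(flat, 1.0, std)
    Z = (X - mean) / std_safe
    Z[:, flat] = 0.0
    res = replace(ds, matrix=Z)
    res.stage = Stage.zscored
    return res


def preprocess(ds: ExpressionDataset, n_hvg: int = 3000, min_genes: int = MIN_GENES_PER_CELL) -> ExpressionDataset:
    """Full pipeline: filter -> library-size normalize -> log+HVG -> z-score."""
    return zscore_genes(log_select_hvg(normalize_library_size(filter_cells_genes(ds, min_genes)), n_hvg))
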
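"""Data model, file I/O, preprocessing and semi-supervised label masking.

The central containers are :class:`ExpressionDataset` (cells x genes matrix,
cells are rows, 0-based indices everywhere), :class:`FactorSpec` (the named
categorical factors the model disentangles, plus the residual dimension) and
:class:`LabelTable` (per-cell integer category labels with an availability
mask; ``-1`` marks a missing label).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "Factor",
    "FactorSpec",
    "LabelTable",
    "read_dataset",
    "write_dataset",
    "normalize",
    "select_hvg",
    "mask_labels",
    "read_labels",
    "write_labels",
]

MISSING = -1


@dataclass
class ExpressionDataset:
    """A cells x genes expression matrix with identifiers and a layer flag.

    Parameters
    ----------
    matrix
        Non-negative ``(n_cells, n_genes)`` array. The ``raw_counts`` layer
        must contain only integral values.
    cell_ids, gene_ids
        Unique row / column identifiers.
    layer
        Either ``"raw_counts"`` or ``"lognorm"``.
    """

    matrix: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer: str = "raw_counts"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, d = self.matrix.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {n} rows")
        if len(self.gene_ids) != d:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {d} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != d:
            raise ValueError("duplicate gene_ids")
        if np.any(self.matrix < 0):
            raise ValueError("negative entries in expression matrix")
        if self.layer not in ("raw_counts", "lognorm"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == "raw_counts" and not np.allclose(
            self.matrix, np.round(self.matrix)
        ):
            raise ValueError("raw_counts layer contains non-integral values")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class Factor:
    """One named categorical factor and the width of its latent code block."""

    name: str
    categories: tuple[str, ...]
    code_dim: int

    def __post_init__(self):
        if len(self.categories) < 2:
            raise ValueError(f"factor {self.name!r} needs >=2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"factor {self.name!r} has duplicate categories")
        if self.code_dim < 1:
            raise ValueError("code_dim must be >=1")

    @property
    def n_categories(self) -> int:
        return len(self.categories)


def default_code_dim(n_categories: int) -> int:
    """Default latent block width: 2 for small factors, 8 for many-category ones."""
    return 2 if n_categories <= 4 else 8


@dataclass(frozen=True)
class FactorSpec:
    """Ordered factors plus the width of the residual latent component."""

    factors: tuple[Factor, ...]
    residual_dim: int = 10

    def __post_init__(self):
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        if self.residual_dim < 1:
            raise ValueError("residual_dim must be >=1")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_categories(self) -> list[int]:
        return [f.n_categories for f in self.factors]

    @property
    def code_dims(self) -> list[int]:
        return [f.code_dim for f in self.factors]

    @property
    def latent_dim(self) -> int:
        return sum(self.code_dims) + self.residual_dim

    @staticmethod
    def build(named_categories: list[tuple[str, list[str]]], residual_dim: int = 10,
              code_dims: dict[str, int] | None = None) -> "FactorSpec":
        """Construct a spec applying the default code-dimension rule."""
        code_dims = code_dims or {}
        factors = tuple(
            Factor(name, tuple(cats), code_dims.get(name, default_code_dim(len(cats))))
            for name, cats in named_categories
        )
        return FactorSpec(factors=factors, residual_dim=residual_dim)

    def to_dict(self) -> dict:
        return {
            "residual_dim": self.residual_dim,
            "factors": [
                {"name": f.name, "categories": list(f.categories), "code_dim": f.code_dim}
                for f in self.factors
            ],
        }

    @staticmethod
    def from_dict(d: dict) -> "FactorSpec":
        return FactorSpec(
            factors=tuple(
                Factor(f["name"], tuple(f["categories"]), int(f["code_dim"]))
                for f in d["factors"]
            ),
            residual_dim=int(d["residual_dim"]),
        )


@dataclass
class LabelTable:
    """Per-cell, per-factor integer labels with an availability mask.

    ``mask[i, j] == 1`` iff the label of factor ``j`` is known for cell ``i``;
    unknown labels are stored as ``-1``.
    """

    labels: np.ndarray
    mask: np.ndarray
    n_categories: list[int] | None = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.labels.shape != self.mask.shape or self.labels.ndim != 2:
            raise ValueError("labels and mask must be equal-shape 2-D arrays")
        if not np.array_equal(self.mask == 1, self.labels >= 0):
            raise ValueError("mask=1 entries must have labels >=0 and mask=0 must be -1")
        if self.n_categories is not None:
            for j, K in enumerate(self.n_categories):
                if np.any(self.labels[:, j] >= K):
                    raise ValueError(f"label out of range for factor {j} (K={K})")

    @property
    def n_cells(self) -> int:
        return self.labels.shape[0]

    @property
    def k(self) -> int:
        return self.labels.shape[1]

    def fully_observed(self) -> bool:
        return bool(np.all(self.mask == 1))

    @staticmethod
    def full(labels: np.ndarray, n_categories: list[int] | None = None) -> "LabelTable":
        labels = np.asarray(labels, dtype=np.int64)
        return LabelTable(labels, np.ones_like(labels, dtype=np.int8), n_categories)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _infer_layer(matrix: np.ndarray) -> str:
    return "raw_counts" if np.allclose(matrix, np.round(matrix)) else "lognorm"


def read_dataset(path: str, format: str | None = None) -> ExpressionDataset:
    """Read an expression matrix from h5ad, a MatrixMarket triplet dir, or CSV.

    The layer is inferred as ``raw_counts`` iff all entries are integral.
    """
    if format is None:
        if str(path).endswith(".h5ad"):
            format = "h5ad"
        elif os.path.isdir(path):
            format = "mtx_dir"
        else:
            format = "csv"
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = np.asarray(X.todense())
        return ExpressionDataset(
            X, list(adata.obs_names), list(adata.var_names), _infer_layer(np.asarray(X))
        )
    if format == "mtx_dir":
        from scipy.io import mmread

        mtx = np.asarray(mmread(os.path.join(path, "matrix.mtx")).todense())
        barcodes = pd.read_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=None
        )[0].tolist()
        feats = pd.read_csv(
            os.path.join(path, "features.tsv"), sep="\t", header=None
        )[0].tolist()
        # CellRanger stores genes x cells
        matrix = mtx.T
        if matrix.shape != (len(barcodes), len(feats)):
            raise ValueError(
                f"matrix shape {mtx.shape} inconsistent with "
                f"{len(barcodes)} barcodes x {len(feats)} features"
            )
        return ExpressionDataset(matrix, barcodes, feats, _infer_layer(matrix))
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        matrix = df.to_numpy(dtype=np.float64)
        if np.any(matrix < 0):
            raise ValueError("negative entries in expression matrix")
        return ExpressionDataset(
            matrix, df.index.tolist(), df.columns.tolist(), _infer_layer(matrix)
        )
    raise ValueError(f"unknown format {format!r}")


def write_dataset(ds: ExpressionDataset, path: str, format: str = "csv") -> None:
    """Write a dataset in any of the supported dialects (inverse of read)."""
    if format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=ds.matrix.copy(),
            obs=pd.DataFrame(index=pd.Index(ds.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(ds.gene_ids, name="gene_id")),
        )
        adata.write_h5ad(path)
    elif format == "mtx_dir":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        os.makedirs(path, exist_ok=True)
        mmwrite(os.path.join(path, "matrix.mtx"), csr_matrix(ds.matrix.T))
        pd.Series(ds.cell_ids).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(ds.gene_ids).to_csv(
            os.path.join(path, "features.tsv"), sep="\t", header=False, index=False
        )
    elif format == "csv":
        pd.DataFrame(ds.matrix, index=ds.cell_ids, columns=ds.gene_ids).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str, spec: FactorSpec) -> LabelTable:
    """Read a label CSV (one column per factor; empty or NA = missing)."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    n = len(df)
    labels = np.full((n, spec.k), MISSING, dtype=np.int64)
    for j, f in enumerate(spec.factors):
        if f.name not in df.columns:
            raise ValueError(f"label table missing column {f.name!r}")
        lut = {c: i for i, c in enumerate(f.categories)}
        col = df[f.name].to_numpy()
        for i, v in enumerate(col):
            if v in ("", "NA", "nan"):
                continue
            if v not in lut:
                raise ValueError(f"unknown category {v!r} for factor {f.name!r}")
            labels[i, j] = lut[v]
    mask = (labels >= 0).astype(np.int8)
    return LabelTable(labels, mask, spec.n_categories)


def write_labels(table: LabelTable, spec: FactorSpec, path: str,
                 cell_ids: list[str] | None = None) -> None:
    cols = {}
    for j, f in enumerate(spec.factors):
        vals = [
            f.categories[v] if v >= 0 else "NA" for v in table.labels[:, j]
        ]
        cols[f.name] = vals
    idx = cell_ids if cell_ids is not None else [f"cell_{i}" for i in range(table.n_cells)]
    pd.DataFrame(cols, index=pd.Index(idx, name="cell_id")).to_csv(path)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def normalize(ds: ExpressionDataset, target_sum: float | None = None) -> ExpressionDataset:
    """Depth-normalize each cell to ``target_sum`` total counts, then log1p.

    ``target_sum`` defaults to the median cell depth. Requires raw counts;
    every cell must have a positive total count.
    """
    if ds.layer != "raw_counts":
        raise ValueError("normalize expects a raw_counts dataset")
    totals = ds.matrix.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {ds.cell_ids[zero[0]]!r} has zero total count")
    if target_sum is None:
        target_sum = float(np.median(totals))
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    scaled = ds.matrix * (target_sum / totals)[:, None]
    return ExpressionDataset(np.log1p(scaled), ds.cell_ids, ds.gene_ids, "lognorm")


def select_hvg(ds: ExpressionDataset, n_top: int) -> ExpressionDataset:
    """Keep the ``n_top`` most variable genes of a lognorm dataset."""
    if ds.layer != "lognorm":
        raise ValueError("select_hvg expects a lognorm dataset")
    if not 0 < n_top <= ds.n_genes:
        raise ValueError("n_top out of range")
    var = ds.matrix.var(axis=0)
    keep = np.sort(np.argsort(var)[::-1][:n_top])
    return ExpressionDataset(
        ds.matrix[:, keep], ds.cell_ids, [ds.gene_ids[i] for i in keep], "lognorm"
    )


# ---------------------------------------------------------------------------
# Label masking
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def mask_labels(full: LabelTable, fraction: float, seed: int,
                per_factor: bool = False) -> LabelTable:
    """Keep labels for a random ``fraction`` of cells, hide the rest.

    By default a labeled cell keeps *all* its factor labels (all-or-none);
    with ``per_factor=True`` each (cell, factor) entry is sampled
    independently instead. The number of kept cells (or entries per factor)
    is ``round(n * fraction)`` with round-half-up; sampling is a simple
    random sample, deterministic given ``seed``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not full.fully_observed():
        raise ValueError("mask_labels requires a fully observed label table")
    n, k = full.labels.shape
    rng = np.random.default_rng(seed)
    labels = np.full_like(full.labels, MISSING)
    mask = np.zeros_like(full.mask)
    n_keep = _round_half_up(n * fraction)
    if per_factor:
        for j in range(k):
            keep = rng.choice(n, size=n_keep, replace=False)
            labels[keep, j] = full.labels[keep, j]
            mask[keep, j] = 1
    else:
        keep = rng.choice(n, size=n_keep, replace=False)
        labels[keep, :] = full.labels[keep, :]
        mask[keep, :] = 1
    return LabelTable(labels, mask, full.n_categories)
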
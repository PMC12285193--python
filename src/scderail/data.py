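"""Count-matrix container shared by all modules.

The model consumes *raw* integer counts; normalization only ever happens
in marker scoring and gene filtering, never before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Raw cell x gene integer counts with identifiers and annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, dense ndarray or scipy sparse,
        shape (n_cells, n_genes).
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    annotations
        Optional per-cell categorical columns (condition, cell state, ...),
        indexed like ``cell_ids``.
    """

    counts: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        n, g = self.counts.shape
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(c) for c in self.gene_ids]
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {n} rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {g} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene_ids")
        dense = self.dense()
        if dense.size and dense.min() < 0:
            raise ValueError("counts must be non-negative")
        if dense.size and np.max(np.abs(dense - np.round(dense))) > 1e-6:
            i, j = np.unravel_index(
                int(np.argmax(np.abs(dense - np.round(dense)))), dense.shape
            )
            raise ValueError(f"non-integer count at cell {i}, gene {j}")
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.cell_ids)
        if len(self.annotations) == 0 and len(self.annotations.columns) == 0:
            self.annotations = pd.DataFrame(index=self.cell_ids)
        if len(self.annotations) != n:
            raise ValueError("annotation length does not match cell count")
        self.annotations = self.annotations.set_axis(self.cell_ids, axis=0)

    # -- basic views ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        x = self.counts
        return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-cell total counts (row sums)."""
        return np.asarray(self.counts.sum(axis=1)).ravel().astype(float)

    # -- manipulation --------------------------------------------------------
    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        missing = [g for g in genes if g not in set(self.gene_ids)]
        if missing:
            raise KeyError(f"unknown genes: {missing[:5]}")
        idx = [self.gene_ids.index(g) for g in genes]
        counts = self.counts[:, idx]
        return CountMatrix(counts, self.cell_ids, list(genes), self.annotations.copy())

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            self.counts[idx, :],
            [self.cell_ids[i] for i in idx],
            self.gene_ids,
            self.annotations.iloc[idx].copy(),
        )

    def reindex_genes(self, gene_ids: list[str]) -> "CountMatrix":
        """Align columns to `gene_ids` (all must be present)."""
        return self.subset_genes(list(gene_ids))

    # -- interop -------------------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=sp.csr_matrix(self.counts) if sp.issparse(self.counts) else self.dense(),
            obs=self.annotations.copy(),
        )
        adata.obs_names = self.cell_ids
        adata.var_names = self.gene_ids
        return adata

    @classmethod
    def from_anndata(cls, adata, layer: str | None = None) -> "CountMatrix":
        X = adata.layers[layer] if layer else adata.X
        ann = adata.obs.copy()
        return cls(X.copy(), list(adata.obs_names), list(adata.var_names), ann)


def median_normalize_log1p(counts: np.ndarray | sp.spmatrix) -> np.ndarray:
    """Median-library-size normalization followed by log1p.

    Used only for marker scoring and differential-expression ranking;
    the generative model itself always sees raw counts.
    """
    x = np.asarray(counts.todense()) if sp.issparse(counts) else np.asarray(counts, float)
    lib = x.sum(axis=1)
    lib = np.where(lib == 0, 1.0, lib)
    target = np.median(lib)
    return np.log1p(x * (target / lib)[:, None])
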
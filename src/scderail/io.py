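"""Readers, writers, gene filtering, and configuration plumbing.

Counts move between three on-disk forms: Matrix Market triplets (with
barcode / gene sidecar files), the AnnData HDF5 dialect, and dense CSV.
Everything a writer emits, the paired reader accepts.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .basis import BasisConfig
from .data import CountMatrix, median_normalize_log1p
from .model import ModelConfig


# ---------------------------------------------------------------------------
# counts


def read_counts(path: str | Path, fmt: str | None = None) -> CountMatrix:
    """Read a CountMatrix from MTX (directory or .mtx file), H5AD, or CSV.

    The format is inferred from the path when not given. Entries must be
    integers (a 1e-6 tolerance absorbs float storage); sparse inputs
    stay sparse.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir() or path.suffix == ".mtx":
            fmt = "mtx"
        elif path.suffix == ".h5ad":
            fmt = "h5ad"
        else:
            fmt = "csv"
    if fmt == "mtx":
        return _read_mtx(path)
    if fmt == "h5ad":
        import anndata as ad

        return CountMatrix.from_anndata(ad.read_h5ad(path))
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        ann_cols = [c for c in df.columns if c.startswith("annotation:")]
        ann = df[ann_cols].rename(columns=lambda c: c[len("annotation:"):])
        counts = df.drop(columns=ann_cols)
        return CountMatrix(
            counts.to_numpy(),
            list(counts.index),
            list(counts.columns),
            ann if ann_cols else None,
        )
    raise ValueError(f"unknown format {fmt!r}")


def _read_mtx(path: Path) -> CountMatrix:
    from scipy.io import mmread

    if path.is_dir():
        mtx_path = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        genes = path / "genes.tsv"
    else:
        mtx_path = path
        barcodes = path.with_name("barcodes.tsv")
        genes = path.with_name("genes.tsv")
    mat = mmread(mtx_path).tocsr()
    cell_ids = barcodes.read_text().split()
    gene_ids = genes.read_text().split()
    if mat.shape != (len(cell_ids), len(gene_ids)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match "
            f"{len(cell_ids)} barcodes x {len(gene_ids)} genes"
        )
    ann_path = (path / "annotations.csv") if path.is_dir() else None
    ann = None
    if ann_path is not None and ann_path.exists():
        ann = pd.read_csv(ann_path, index_col=0)
    return CountMatrix(mat, cell_ids, gene_ids, ann)


def write_counts(data: CountMatrix, path: str | Path, fmt: str = "mtx"):
    """Write counts in the requested format (mtx directory, h5ad, or csv)."""
    path = Path(path)
    if fmt == "mtx":
        from scipy.io import mmwrite

        path.mkdir(parents=True, exist_ok=True)
        mmwrite(path / "matrix.mtx", sp.coo_matrix(data.counts))
        (path / "barcodes.tsv").write_text("\n".join(data.cell_ids) + "\n")
        (path / "genes.tsv").write_text("\n".join(data.gene_ids) + "\n")
        if len(data.annotations.columns):
            data.annotations.to_csv(path / "annotations.csv")
    elif fmt == "h5ad":
        data.to_anndata().write_h5ad(path)
    elif fmt == "csv":
        df = pd.DataFrame(data.dense(), index=data.cell_ids, columns=data.gene_ids)
        for col in data.annotations.columns:
            df[f"annotation:{col}"] = data.annotations[col].to_numpy()
        df.to_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# gene filtering


def filter_genes(
    data: CountMatrix,
    labels: np.ndarray,
    top_n: int = 400,
    markers: list[str] | None = None,
) -> list[str]:
    """Union over clusters of the top differentially expressed genes.

    Genes are ranked per cluster by a Welch t-statistic (cluster vs rest)
    on median-normalized log1p expression; each cluster contributes its
    ``top_n`` genes, known markers are pooled in, and the input gene
    order is preserved.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    xn = median_normalize_log1p(data.counts)
    selected: set[str] = set(markers or [])
    for c in uniq:
        a, b = xn[labels == c], xn[labels != c]
        na, nb = len(a), len(b)
        va = a.var(axis=0, ddof=1) if na > 1 else np.zeros(xn.shape[1])
        vb = b.var(axis=0, ddof=1) if nb > 1 else np.zeros(xn.shape[1])
        denom = np.sqrt(va / max(na, 1) + vb / max(nb, 1))
        denom = np.where(denom == 0, np.inf, denom)
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
        # magnitude ranking: a gene strongly down in a cluster is as
        # informative as one strongly up
        top = np.argsort(-np.abs(t))[:top_n]
        selected.update(data.gene_ids[i] for i in top)
    return [g for g in data.gene_ids if g in selected]


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    basis: BasisConfig = dataclasses.field(default_factory=BasisConfig)
    # trajectory parameters
    n_neighbors: int = 15
    resolution: float = 0.7
    spacing: float = 0.05
    start_markers: list[str] = dataclasses.field(default_factory=list)
    end_markers: list[str] = dataclasses.field(default_factory=list)
    pattern_genes: list[str] = dataclasses.field(default_factory=list)
    condition_column: str | None = None
    disruption_pair: list[str] = dataclasses.field(default_factory=list)
    # optional post-hoc rotation of the 2D space
    rotate_column: str | None = None
    rotate_order: list[str] = dataclasses.field(default_factory=list)
    rotate_axis: int = 0
    # bookkeeping
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        model = ModelConfig(**d.pop("model", {}))
        basis = BasisConfig(**d.pop("basis", {}))
        return cls(model=model, basis=basis, **d)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def write_config(config: RunConfig, path: str | Path):
    """Serialize a RunConfig as TOML (lossless round trip with read_config)."""
    lines = []
    d = config.to_dict()
    model = d.pop("model")
    basis = d.pop("basis")
    for k, v in d.items():
        if v is None:
            continue
        lines.append(f"{k} = {_toml_value(v)}")
    for section, vals in (("model", model), ("basis", basis)):
        lines.append(f"\n[{section}]")
        for k, v in vals.items():
            lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        return RunConfig.from_dict(tomllib.load(fh))
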
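"""End-to-end pipeline: train -> embed -> (rotate) -> trajectory ->
patterns -> basis -> disruption, with stage-level resume.

Every stage writes its artifact into the output directory; a stage is
skipped when its artifact already exists, so deleting a single file and
re-running recomputes only what is missing. The resolved configuration,
tool version and per-stage wall times are written alongside.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .basis import PatternMatrix, disruption_scores, fit_basis
from .data import CountMatrix
from .io import RunConfig, write_config
from .model import Embedding, HierarchicalNBVAE, encode_order, fit, rotate_space
from .trajectory import (
    TrajectoryPath,
    assign_path_time,
    build_cluster_graph,
    cluster_latent,
    find_path,
    interpolate_path,
    reconstruct_gene_patterns,
)

logger = logging.getLogger("scderail")

ARTIFACTS = {
    "train": "model",
    "embed": "embedding.tsv",
    "rotate": "embedding_rotated.tsv",
    "trajectory": "paths.tsv",
    "times": "times.tsv",
    "patterns": "patterns.csv",
    "basis": "basis",
    "disrupt": "disruption.csv",
}


def _stage_done(out: Path, stage: str) -> bool:
    p = out / ARTIFACTS[stage]
    return p.exists() and (not p.is_dir() or any(p.iterdir()))


def run_pipeline(config: RunConfig, data: CountMatrix, out_dir: str | Path) -> Path:
    """Run (or resume) the full analysis, returning the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_config(config, out / "config.toml")
    (out / "version.txt").write_text(__version__ + "\n")
    timings: dict[str, float] = {}
    log_path = out / "run_log.txt"

    def stage(name: str):
        done = _stage_done(out, name)
        if done:
            logger.info("stage %s: artifact present, skipping", name)
        return not done

    def mark(name: str, t0: float):
        timings[name] = round(time.time() - t0, 3)
        with open(log_path, "a") as fh:
            fh.write(
                f"{name}\tseed={config.seed}\twall_time={timings[name]}s\n"
            )

    config.model.seed = config.seed
    config.basis.seed = config.seed

    # train ------------------------------------------------------------------
    model_dir = out / ARTIFACTS["train"]
    if stage("train"):
        t0 = time.time()
        model = fit(data, config.model)
        model.save(model_dir)
        mark("train", t0)
    else:
        model = HierarchicalNBVAE.load(model_dir)

    # embed ------------------------------------------------------------------
    emb_path = out / ARTIFACTS["embed"]
    if stage("embed"):
        t0 = time.time()
        embedding = model.encode(data)
        embedding.to_frame().to_csv(emb_path, sep="\t")
        mark("embed", t0)
    else:
        embedding = Embedding.from_frame(pd.read_csv(emb_path, sep="\t", index_col=0))
        embedding.cell_ids = list(data.cell_ids)

    # rotate (optional) ------------------------------------------------------
    if config.rotate_column:
        if stage("rotate"):
            t0 = time.time()
            codes = encode_order(
                data.annotations[config.rotate_column], config.rotate_order
            )
            embedding = rotate_space(embedding, [(codes, config.rotate_axis)])
            embedding.to_frame().to_csv(out / ARTIFACTS["rotate"], sep="\t")
            mark("rotate", t0)
        else:
            embedding = Embedding.from_frame(
                pd.read_csv(out / ARTIFACTS["rotate"], sep="\t", index_col=0)
            )
            embedding.cell_ids = list(data.cell_ids)

    # trajectory -------------------------------------------------------------
    conditions = (
        data.annotations[config.condition_column].astype(str).to_numpy()
        if config.condition_column
        else np.array(["all"] * data.n_cells)
    )
    paths_file = out / ARTIFACTS["trajectory"]
    if stage("trajectory"):
        t0 = time.time()
        labels = cluster_latent(
            embedding.z, config.n_neighbors, config.resolution, seed=config.seed
        )
        graph = build_cluster_graph(embedding, labels)
        pd.DataFrame(
            {"cell_id": data.cell_ids, "cluster": labels}
        ).to_csv(out / "clusters.csv", index=False)
        frames = []
        for cond in sorted(set(conditions)):
            sub = data.subset_cells(conditions == cond)
            sub_labels = labels[conditions == cond]
            # marker scoring restricted to this condition's cells, but on
            # the global cluster structure
            graph_cond = graph
            seq = find_path(
                _restrict_graph(graph_cond, sub_labels),
                sub,
                config.start_markers,
                config.end_markers,
            )
            path = interpolate_path(graph, seq, config.spacing, condition=cond)
            frames.append(path.to_frame())
        pd.concat(frames, ignore_index=True).to_csv(paths_file, sep="\t", index=False)
        mark("trajectory", t0)
    paths_df = pd.read_csv(paths_file, sep="\t")
    paths = {
        str(cond): TrajectoryPath.from_frame(grp)
        for cond, grp in paths_df.groupby("condition")
    }

    # per-cell time ----------------------------------------------------------
    if stage("times"):
        t0 = time.time()
        times = assign_path_time(embedding, paths, conditions)
        times.to_csv(out / ARTIFACTS["times"], index=False)
        mark("times", t0)

    # gene patterns ----------------------------------------------------------
    pat_file = out / ARTIFACTS["patterns"]
    if stage("patterns"):
        t0 = time.time()
        genes = config.pattern_genes or _top_variable_genes(data, 30)
        lib = float(np.median(data.library_sizes))
        frames = []
        for cond, path in paths.items():
            ps = reconstruct_gene_patterns(
                model, path, genes, library_size=lib, seed=config.seed
            )
            frames.append(ps.to_frame())
        pd.concat(frames, ignore_index=True).to_csv(pat_file, index=False)
        mark("patterns", t0)

    # basis ------------------------------------------------------------------
    basis_dir = out / ARTIFACTS["basis"]
    if stage("basis"):
        t0 = time.time()
        pat = pd.read_csv(pat_file)
        patterns = PatternMatrix.from_long(pat, value_col="mean")
        bfit = fit_basis(patterns, config.basis)
        basis_dir.mkdir(exist_ok=True)
        _write_basis(bfit, basis_dir)
        mark("basis", t0)

    # disruption -------------------------------------------------------------
    if stage("disrupt"):
        t0 = time.time()
        bfit = _read_basis(basis_dir)
        pair = tuple(config.disruption_pair) or tuple(bfit.condition_ids[:2])
        if len(bfit.condition_ids) >= 2:
            table = disruption_scores(bfit, pair)
            table.to_csv(out / ARTIFACTS["disrupt"], index=False)
        else:
            pd.DataFrame(
                columns=["gene", "scale_disruption", "shape_disruption", "combined_disruption"]
            ).to_csv(out / ARTIFACTS["disrupt"], index=False)
        mark("disrupt", t0)

    (out / "timings.json").write_text(json.dumps(timings, indent=2))
    return out


def _restrict_graph(graph, sub_labels):
    """View of the cluster graph whose label vector covers one condition."""
    import copy

    g = copy.copy(graph)
    g.labels = np.asarray(sub_labels, int)
    return g


def _top_variable_genes(data: CountMatrix, n: int) -> list[str]:
    from .data import median_normalize_log1p

    xn = median_normalize_log1p(data.counts)
    order = np.argsort(-xn.var(axis=0))[:n]
    return [data.gene_ids[i] for i in sorted(order)]


def _write_basis(bfit, path: Path):
    rows = []
    for k in range(len(bfit.basis_values)):
        rows.append(pd.DataFrame({"k": k, "time": bfit.time_grid, "value": bfit.basis_values[k]}))
    pd.concat(rows, ignore_index=True).to_csv(path / "bases.csv", index=False)
    wrows = []
    for i, g in enumerate(bfit.gene_ids):
        for j, c in enumerate(bfit.condition_ids):
            for k in range(bfit.weights.shape[2]):
                wrows.append((g, c, k, bfit.weights[i, j, k]))
    pd.DataFrame(wrows, columns=["gene", "condition", "k", "beta"]).to_csv(
        path / "weights.csv", index=False
    )
    srows = [
        (g, c, bfit.scales[i, j])
        for i, g in enumerate(bfit.gene_ids)
        for j, c in enumerate(bfit.condition_ids)
    ]
    pd.DataFrame(srows, columns=["gene", "condition", "scale"]).to_csv(
        path / "scales.csv", index=False
    )
    (path / "meta.json").write_text(
        json.dumps({"noise_variance": bfit.noise_variance})
    )


def _read_basis(path: Path):
    from .basis import BasisFit

    bases = pd.read_csv(path / "bases.csv")
    weights = pd.read_csv(path / "weights.csv")
    scales = pd.read_csv(path / "scales.csv")
    meta = json.loads((path / "meta.json").read_text())
    genes = list(dict.fromkeys(weights["gene"].astype(str)))
    conds = list(dict.fromkeys(weights["condition"].astype(str)))
    ks = sorted(bases["k"].unique())
    grid = bases[bases["k"] == ks[0]]["time"].to_numpy()
    bmat = np.stack([bases[bases["k"] == k]["value"].to_numpy() for k in ks])
    wmat = np.zeros((len(genes), len(conds), len(ks)))
    smat = np.zeros((len(genes), len(conds)))
    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: j for j, c in enumerate(conds)}
    for _, row in weights.iterrows():
        wmat[gi[str(row["gene"])], ci[str(row["condition"])], int(row["k"])] = row["beta"]
    for _, row in scales.iterrows():
        smat[gi[str(row["gene"])], ci[str(row["condition"])]] = row["scale"]
    return BasisFit(
        basis_values=bmat,
        weights=wmat,
        scales=smat,
        noise_variance=meta["noise_variance"],
        time_grid=grid,
        gene_ids=genes,
        condition_ids=conds,
    )
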
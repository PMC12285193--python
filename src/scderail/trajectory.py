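"""Trajectories in the 2D embedding space and gene patterns along them.

The construction follows a simple recipe: cluster cells on the latent
factors ``z`` (they carry the finer-grained information), compute a
minimum spanning tree over cluster centroids using distances in the 2D
space ``v`` (which carries the global geometry), pick start and end
clusters from marker-gene scores, walk the unique tree path between
them, and linearly interpolate the centroid polyline. The cumulative
arc length along a path is the pseudotime coordinate ("path time");
because all conditions share one embedding, per-condition paths are
directly comparable without any warping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .data import CountMatrix, median_normalize_log1p
from .model import Embedding, HierarchicalNBVAE


# ---------------------------------------------------------------------------
# clustering and cluster graph


def cluster_latent(
    z: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 0.7,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community labels on a kNN graph of the latent factors.

    Returns contiguous integer labels 0..K-1; deterministic under seed.
    """
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    z = np.asarray(z, float)
    n = len(z)
    if n < n_neighbors + 1:
        raise ValueError("need more cells than n_neighbors")
    if np.allclose(z, z[0]):
        warnings.warn("all latent vectors identical; returning a single cluster")
        return np.zeros(n, dtype=int)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(z)
    _, idx = nn.kneighbors(z)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=int)
    # relabel to contiguous ids ordered by first occurrence
    _, labels = np.unique(labels, return_inverse=True)
    return labels


@dataclass
class ClusterGraph:
    """Cluster centroids in both spaces plus the MST over v-centroids."""

    labels: np.ndarray
    centroids_v: np.ndarray
    centroids_z: np.ndarray
    mst_edges: list[tuple[int, int, float]]

    @property
    def n_clusters(self) -> int:
        return len(self.centroids_v)

    def as_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_clusters))
        g.add_weighted_edges_from(self.mst_edges)
        return g


def build_cluster_graph(embedding: Embedding, labels: np.ndarray) -> ClusterGraph:
    """Per-cluster centroids and the minimum spanning tree between them,
    with edge weights given by Euclidean distance in the 2D space."""
    labels = np.asarray(labels, int)
    k = labels.max() + 1
    if k < 2:
        raise ValueError("need at least 2 clusters")
    centroids_v = np.stack([embedding.v[labels == c].mean(axis=0) for c in range(k)])
    centroids_z = np.stack([embedding.z[labels == c].mean(axis=0) for c in range(k)])
    complete = nx.Graph()
    for a in range(k):
        for b in range(a + 1, k):
            complete.add_edge(a, b, weight=float(np.linalg.norm(centroids_v[a] - centroids_v[b])))
    mst = nx.minimum_spanning_tree(complete)
    edges = [(a, b, d["weight"]) for a, b, d in mst.edges(data=True)]
    return ClusterGraph(labels, centroids_v, centroids_z, edges)


# ---------------------------------------------------------------------------
# path finding


def score_markers(
    counts: CountMatrix, labels: np.ndarray, markers: list[str]
) -> np.ndarray:
    """Per-cluster mean of median-normalized log1p expression over markers."""
    missing = [m for m in markers if m not in set(counts.gene_ids)]
    if missing:
        raise KeyError(f"marker genes not in data: {missing}")
    xn = median_normalize_log1p(counts.counts)
    cols = [counts.gene_ids.index(m) for m in markers]
    labels = np.asarray(labels, int)
    k = labels.max() + 1
    # clusters with no cells (e.g. when scoring one condition's cells
    # against the global clustering) can never be an endpoint
    return np.array(
        [
            xn[labels == c][:, cols].mean() if np.any(labels == c) else -np.inf
            for c in range(k)
        ]
    )


def find_path(
    graph: ClusterGraph,
    counts: CountMatrix | None = None,
    start_markers: list[str] | None = None,
    end_markers: list[str] | None = None,
    cluster_sequence: list[int] | None = None,
) -> list[int]:
    """Cluster sequence of a trajectory through the MST.

    Either give marker genes for both ends (the start/end cluster is the
    argmax of the mean normalized marker expression) or pass an explicit
    ``cluster_sequence`` for manually specified paths.
    """
    if cluster_sequence is not None:
        return [int(c) for c in cluster_sequence]
    if counts is None or start_markers is None or end_markers is None:
        raise ValueError("need counts plus start and end markers, or an explicit sequence")
    start_scores = score_markers(counts, graph.labels, start_markers)
    end_scores = score_markers(counts, graph.labels, end_markers)
    start, end = int(np.argmax(start_scores)), int(np.argmax(end_scores))
    if start == end:
        raise ValueError(
            f"start and end markers select the same cluster {start}; "
            f"start scores {start_scores.round(3).tolist()}, "
            f"end scores {end_scores.round(3).tolist()}"
        )
    return [int(c) for c in nx.shortest_path(graph.as_networkx(), start, end)]


@dataclass
class TrajectoryPath:
    """Polyline through ordered cluster centroids, parameterized by
    cumulative arc length (the pseudotime axis)."""

    cluster_sequence: list[int]
    points: np.ndarray
    times: np.ndarray
    condition: str | None = None

    @property
    def length(self) -> float:
        return float(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "point": np.arange(len(self.times)),
                "v1": self.points[:, 0],
                "v2": self.points[:, 1],
                "time": self.times,
            }
        )
        if self.condition is not None:
            df["condition"] = self.condition
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrajectoryPath":
        cond = str(df["condition"].iloc[0]) if "condition" in df else None
        return cls(
            cluster_sequence=[],
            points=df[["v1", "v2"]].to_numpy(float),
            times=df["time"].to_numpy(float),
            condition=cond,
        )


def interpolate_path(
    graph: ClusterGraph,
    cluster_sequence: list[int],
    spacing: float = 0.05,
    condition: str | None = None,
) -> TrajectoryPath:
    """Sample the centroid polyline every `spacing` arc-length units.

    Segment endpoints (the centroids) are always included, so the final
    time equals the exact total polyline length.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if len(cluster_sequence) < 2:
        raise ValueError("need at least two clusters in the sequence")
    verts = graph.centroids_v[np.asarray(cluster_sequence, int)]
    points = [verts[0]]
    times = [0.0]
    t0 = 0.0
    for a, b in zip(verts[:-1], verts[1:]):
        seg = float(np.linalg.norm(b - a))
        n_steps = int(np.floor(seg / spacing + 1e-9))
        for s in range(1, n_steps + 1):
            frac = s * spacing / seg
            if frac >= 1.0 - 1e-12:
                break
            points.append(a + frac * (b - a))
            times.append(t0 + s * spacing)
        points.append(b)
        times.append(t0 + seg)
        t0 += seg
    return TrajectoryPath(
        cluster_sequence=[int(c) for c in cluster_sequence],
        points=np.asarray(points),
        times=np.asarray(times),
        condition=condition,
    )


# ---------------------------------------------------------------------------
# time assignment


def assign_path_time(
    embedding: Embedding,
    paths: dict[str, TrajectoryPath],
    condition_labels: np.ndarray | list[str] | None = None,
) -> pd.DataFrame:
    """Project each cell onto its condition's path.

    Each cell receives the time of the nearest polyline point of the
    path for its own condition, plus the Euclidean distance to it.
    Ties go to the smaller time. With a single path and no labels, all
    cells use that path.
    """
    if condition_labels is None:
        if len(paths) != 1:
            raise ValueError("condition_labels required with multiple paths")
        condition_labels = [next(iter(paths))] * len(embedding.cell_ids)
    condition_labels = [str(c) for c in condition_labels]
    missing = sorted(set(condition_labels) - set(paths))
    if missing:
        raise ValueError(f"no trajectory for condition(s): {missing}")
    times = np.empty(len(condition_labels))
    dists = np.empty(len(condition_labels))
    for cond, path in paths.items():
        mask = np.array([c == cond for c in condition_labels])
        if not mask.any():
            continue
        diff = embedding.v[mask][:, None, :] - path.points[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        best = np.argmin(d, axis=1)  # argmin takes the first = smallest time
        times[mask] = path.times[best]
        dists[mask] = d[np.arange(mask.sum()), best]
    return pd.DataFrame(
        {
            "cell_id": embedding.cell_ids,
            "condition": condition_labels,
            "time": times,
            "distance": dists,
        }
    )


# ---------------------------------------------------------------------------
# gene patterns


@dataclass
class GenePatternSet:
    """Decoded expression of selected genes along one path, with
    interquartile uncertainty bands from latent sampling."""

    genes: list[str]
    time_grid: np.ndarray
    mean: np.ndarray  # gene x time
    q25: np.ndarray
    q50: np.ndarray
    q75: np.ndarray
    library_size: float
    condition: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.genes):
            df = pd.DataFrame(
                {
                    "gene": g,
                    "time": self.time_grid,
                    "mean": self.mean[i],
                    "q25": self.q25[i],
                    "q50": self.q50[i],
                    "q75": self.q75[i],
                }
            )
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        if self.condition is not None:
            out["condition"] = self.condition
        return out


def reconstruct_gene_patterns(
    model: HierarchicalNBVAE,
    path: TrajectoryPath,
    genes: list[str] | None = None,
    n_samples: int = 100,
    library_size: float = 1.0,
    seed: int = 0,
) -> GenePatternSet:
    """Decode expression along a path: mean from the deterministic
    decoder chain, bands from 100 sampled latent draws per point."""
    genes = list(genes) if genes is not None else list(model.gene_ids)
    unknown = [g for g in genes if g not in set(model.gene_ids)]
    if unknown:
        raise KeyError(f"genes not in the model: {unknown}")
    cols = [model.gene_ids.index(g) for g in genes]
    mean, _ = model.decode(path.points, library_size=library_size)
    bands = model.decode_with_uncertainty(
        path.points, n_samples=n_samples, seed=seed, library_size=library_size
    )
    return GenePatternSet(
        genes=genes,
        time_grid=path.times.copy(),
        mean=mean[:, cols].T,
        q25=bands["q25"][:, cols].T,
        q50=bands["q50"][:, cols].T,
        q75=bands["q75"][:, cols].T,
        library_size=float(library_size),
        condition=path.condition,
    )


# ---------------------------------------------------------------------------
# peak calling


def detect_peaks(pattern: np.ndarray, smooth_sigma: float = 3.0) -> list[int]:
    """Indices of expression peaks along a (uniform) time grid.

    The series is Gaussian-smoothed (detection only), local maxima are
    points where the first difference flips from positive to negative,
    and maxima below the midrange (mean of min and max) are dropped.
    The start is added when expression starts above midrange with a
    falling first step, or when the global maximum sits at the start;
    the end is added when the global maximum sits at the end. A constant
    series has no peaks.
    """
    from scipy.ndimage import gaussian_filter1d

    y = np.asarray(pattern, float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("pattern must be a 1D series of length >= 3")
    if np.allclose(y, y[0]):
        return []
    s = gaussian_filter1d(y, smooth_sigma, mode="nearest")
    midrange = 0.5 * (s.min() + s.max())
    d = np.diff(s)
    peaks = [
        i
        for i in range(1, len(s) - 1)
        if d[i - 1] > 0 and d[i] <= 0 and s[i] >= midrange
    ]
    argmax = int(np.argmax(s))
    if (s[0] >= midrange and d[0] < 0) or argmax == 0:
        if 0 not in peaks:
            peaks.insert(0, 0)
    if argmax == len(s) - 1:
        peaks.append(len(s) - 1)
    return peaks
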
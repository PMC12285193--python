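"""Ground-truth trajectory simulator and embedding-quality metrics.

The simulator emulates a forked differentiation process: 2D cell states
sampled uniformly along a trunk that splits into two arms, thinned
inside designated transition windows (rare intermediate states),
perturbed with Gaussian noise and pushed through a fixed random
nonlinear map into high-dimensional expression. The first coordinate of
the state doubles as the ground-truth pseudotime.

The metrics score any embedding against such ground truth: a
global-structure preservation score (mean Kendall-tau between
cross-cluster distance profiles), an ordering score for annotated
maturation stages, and a divergence score for the expected
far-termini / close-origins geometry of a diseased-vs-normal pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import kendalltau

from .data import CountMatrix


# ---------------------------------------------------------------------------
# fork geometry


@dataclass
class ForkSpec:
    """Piecewise-linear fork: a trunk splitting into two arms.

    ``transition_intervals`` are arc-length windows (measured along a
    branch path = trunk + one arm) inside which sampled cells are
    retained only with the transition density.
    """

    trunk: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (4.0, 0.0))
    arm_ends: tuple[tuple[float, float], tuple[float, float]] = ((8.0, 2.0), (8.0, -2.0))
    transition_intervals: list[tuple[float, float]] = field(
        default_factory=lambda: [(3.5, 4.5)]
    )

    @property
    def trunk_length(self) -> float:
        a, b = np.array(self.trunk[0]), np.array(self.trunk[1])
        return float(np.linalg.norm(b - a))

    def branch_point(self, branch: int, t: np.ndarray) -> np.ndarray:
        """Position at arc length t along branch path (trunk then arm)."""
        a, b = np.array(self.trunk[0]), np.array(self.trunk[1])
        e = np.array(self.arm_ends[branch])
        lt = self.trunk_length
        la = float(np.linalg.norm(e - b))
        t = np.asarray(t, float)
        on_trunk = t <= lt
        frac_t = np.clip(t / lt, 0, 1)[:, None]
        frac_a = np.clip((t - lt) / la, 0, 1)[:, None]
        return np.where(on_trunk[:, None], a + frac_t * (b - a), b + frac_a * (e - b))

    def branch_length(self, branch: int) -> float:
        b = np.array(self.trunk[1])
        e = np.array(self.arm_ends[branch])
        return self.trunk_length + float(np.linalg.norm(e - b))

    def in_transition(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        mask = np.zeros(t.shape, bool)
        for lo, hi in self.transition_intervals:
            mask |= (t >= lo) & (t <= hi)
        return mask


@dataclass
class SimulatedDataset:
    """Ground-truth states, their noisy versions, and (optionally) the
    mapped expression. ``pseudotime`` is the first state coordinate."""

    true_states: np.ndarray
    pseudotime: np.ndarray
    noisy_states: np.ndarray
    branch_label: np.ndarray
    expression: np.ndarray | None
    spec: dict

    @property
    def n_cells(self) -> int:
        return len(self.true_states)


def simulate_states(
    n: int,
    fork: ForkSpec | None = None,
    transition_density: float = 1.0,
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> SimulatedDataset:
    """Sample `n` candidate locations along the fork, thin the transition
    windows to `transition_density`, and add isotropic Gaussian noise.

    ``transition_density`` is the retention probability inside the
    windows (1 keeps everything, 0 removes all transition cells), so the
    returned dataset generally has fewer than `n` cells.
    """
    if not (0.0 <= transition_density <= 1.0):
        raise ValueError("transition_density must lie in [0, 1]")
    if n < 10:
        raise ValueError("n must be >= 10")
    fork = fork or ForkSpec()
    rng = np.random.default_rng(seed)
    branch = rng.integers(0, 2, n)
    lengths = np.array([fork.branch_length(0), fork.branch_length(1)])
    t = rng.uniform(0, lengths[branch])
    keep = ~fork.in_transition(t) | (rng.uniform(size=n) < transition_density)
    t, branch = t[keep], branch[keep]
    states = np.empty((len(t), 2))
    for b in (0, 1):
        m = branch == b
        states[m] = fork.branch_point(b, t[m])
    noisy = states + rng.normal(0.0, noise_sigma, states.shape)
    return SimulatedDataset(
        true_states=states,
        pseudotime=states[:, 0].copy(),
        noisy_states=noisy,
        branch_label=branch,
        expression=None,
        spec={
            "n": n,
            "transition_density": transition_density,
            "noise_sigma": noise_sigma,
            "seed": seed,
            "fork": asdict(fork),
        },
    )


# ---------------------------------------------------------------------------
# random expression map


def map_to_expression(
    states: np.ndarray,
    d: int = 500,
    hidden: tuple[int, ...] = (64, 64),
    seed: int = 0,
) -> np.ndarray:
    """Fixed random feed-forward map from 2D states to d-dim expression.

    Weights are drawn once from the seed (centered normals, variance
    1/fan-in); identical states always map to identical outputs.
    """
    if d < 2:
        raise ValueError("d must be >= 2")
    rng = np.random.default_rng(seed)
    x = np.asarray(states, float)
    last = x.shape[1]
    for h in hidden:
        w = rng.normal(0, np.sqrt(1.0 / last), (last, h))
        b = rng.normal(0, 0.1, h)
        x = np.maximum(x @ w + b, 0.0)
        last = h
    w = rng.normal(0, np.sqrt(1.0 / last), (last, d))
    b = rng.normal(0, 0.1, d)
    return x @ w + b


def expression_to_counts(
    expression: np.ndarray,
    median_depth: float = 5000.0,
    depth_sigma: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Turn real-valued expression into raw counts.

    Softplus makes the random-map output a positive rate, each cell's
    rates are scaled to a log-normal sequencing depth, and counts are
    drawn Poisson. This is the bridge from the simulator's real-valued
    expression to the count model's input.
    """
    rng = np.random.default_rng(seed)
    rates = np.logaddexp(0.0, np.asarray(expression, float))
    depths = np.exp(rng.normal(np.log(median_depth), depth_sigma, len(rates)))
    rates = rates / rates.sum(axis=1, keepdims=True) * depths[:, None]
    return rng.poisson(rates).astype(np.int64)


def simulated_count_matrix(sim: SimulatedDataset, counts: np.ndarray) -> CountMatrix:
    """Wrap simulated counts with ids and branch annotations."""
    import pandas as pd

    return CountMatrix(
        counts,
        [f"cell{i}" for i in range(len(counts))],
        [f"g{j}" for j in range(counts.shape[1])],
        pd.DataFrame({"branch": sim.branch_label.astype(str)}),
    )


# ---------------------------------------------------------------------------
# metrics


def global_preservation(
    true_states: np.ndarray,
    latent: np.ndarray,
    n_clusters: int = 20,
    seed: int = 0,
) -> float:
    """Mean Kendall-tau between cross-cluster distance profiles.

    Cells are k-means clustered in the ground-truth space; for each
    ordered cluster pair the sum of all cross-cluster pairwise Euclidean
    distances is computed in both spaces; the score is the mean over
    clusters of the Kendall-tau correlation between the two distance
    profiles. Maximum 1 for any isometry (up to scale) of the truth.
    """
    from scipy.spatial.distance import cdist
    from sklearn.cluster import KMeans

    true_states = np.asarray(true_states, float)
    latent = np.asarray(latent, float)
    if len(true_states) != len(latent):
        raise ValueError("true_states and latent must be row-aligned")
    if len(true_states) < n_clusters:
        raise ValueError("need at least n_clusters cells")
    for attempt in range(2):
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(true_states)
        if len(np.unique(labels)) == n_clusters:
            break
    else:
        raise RuntimeError("k-means produced an empty cluster twice")
    groups = [np.flatnonzero(labels == c) for c in range(n_clusters)]
    d_true = np.zeros((n_clusters, n_clusters))
    d_lat = np.zeros((n_clusters, n_clusters))
    for i in range(n_clusters):
        for j in range(i + 1, n_clusters):
            d_true[i, j] = d_true[j, i] = cdist(
                true_states[groups[i]], true_states[groups[j]]
            ).sum()
            d_lat[i, j] = d_lat[j, i] = cdist(
                latent[groups[i]], latent[groups[j]]
            ).sum()
    # each cluster's profile covers the *other* clusters (the self
    # distance is identically 0 in both spaces and carries no signal)
    taus = []
    for i in range(n_clusters):
        mask = np.arange(n_clusters) != i
        taus.append(kendalltau(d_true[i, mask], d_lat[i, mask]).statistic)
    return float(np.mean(taus))


def _group_distance(latent: np.ndarray, labels: np.ndarray, a, b) -> float:
    """Mean pairwise Euclidean distance between cells of groups a and b."""
    from scipy.spatial.distance import cdist

    ga = latent[np.asarray(labels) == a]
    gb = latent[np.asarray(labels) == b]
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError(f"empty group in pair ({a}, {b})")
    return float(cdist(ga, gb).mean())


def ordering_score(latent: np.ndarray, labels, order: list) -> float:
    """Ratio of non-consecutive to consecutive between-state distances.

    With states perfectly aligned along ``order`` the triangle
    inequality makes this ratio maximal; higher means better ordering.
    """
    if len(order) < 3:
        raise ValueError("order must list at least 3 states")
    latent = np.asarray(latent, float)
    present = set(np.asarray(labels).tolist())
    missing = [o for o in order if o not in present]
    if missing:
        raise ValueError(f"states not present in labels: {missing}")
    num = den = 0.0
    for i1 in range(len(order)):
        for i2 in range(i1 + 1, len(order)):
            d = _group_distance(latent, labels, order[i1], order[i2])
            if i2 - i1 > 1:
                num += d
            else:
                den += d
    return num / den


def divergence_score(
    latent: np.ndarray,
    labels,
    order_a: list,
    order_b: list,
    anchor_pair: tuple,
) -> float:
    """Far-termini / close-origins score for two condition trajectories.

    Sums distances between all non-anchor state pairs across the two
    conditions and subtracts twice the anchor distance; higher when the
    trajectories share an origin but diverge elsewhere.
    """
    a1, a2 = anchor_pair
    present = set(np.asarray(labels).tolist())
    for lab in list(order_a) + list(order_b):
        if lab not in present:
            raise ValueError(f"state {lab!r} not present in labels")
    if a1 not in order_a or a2 not in order_b:
        raise ValueError("anchor labels must belong to their condition's order")
    latent = np.asarray(latent, float)
    total = 0.0
    for c1 in order_a:
        if c1 == a1:
            continue
        for c2 in order_b:
            if c2 == a2:
                continue
            total += _group_distance(latent, labels, c1, c2)
    return total - 2.0 * _group_distance(latent, labels, a1, a2)


# ---------------------------------------------------------------------------
# mutation proportion


def mutation_proportion(m, w) -> np.ndarray | float:
    """Smoothed mutant fraction m/(m+w+1e-10) among neighbor calls."""
    m = np.asarray(m, float)
    w = np.asarray(w, float)
    if np.any(m < 0) or np.any(w < 0):
        raise ValueError("counts must be non-negative")
    out = m / (m + w + 1e-10)
    return out if out.ndim else float(out)


def neighborhood_mutation_proportion(
    counts: CountMatrix,
    status: np.ndarray,
    k: int = 30,
    n_components: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell mutant proportion among the k nearest neighbors in a
    truncated-SVD space of the normalized counts.

    ``status`` holds per-cell calls: "mut", "wt", or anything else for
    unassigned cells (counted in neither m nor w).
    """
    from sklearn.decomposition import TruncatedSVD
    from sklearn.neighbors import NearestNeighbors

    from .data import median_normalize_log1p

    n = counts.n_cells
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    status = np.asarray([str(s) for s in status])
    xn = median_normalize_log1p(counts.counts)
    n_comp = min(n_components, min(xn.shape) - 1)
    emb = TruncatedSVD(n_components=n_comp, random_state=seed).fit_transform(xn)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    neigh = idx[:, 1:]
    m = (status[neigh] == "mut").sum(axis=1)
    w = (status[neigh] == "wt").sum(axis=1)
    return mutation_proportion(m, w)


# ---------------------------------------------------------------------------
# ground-truth model for recovery studies


def synthetic_model(
    n_genes: int = 200,
    dim_z: int = 10,
    dim_v: int = 2,
    seed: int = 7,
    dispersion: float = 20.0,
    expression_contrast: float = 2.0,
):
    """A known generative model used as ground truth in recovery studies.

    A freshly initialized hierarchical VAE with per-gene dispersion set
    to a realistic value and the expression decoder sharpened so genes
    vary meaningfully across the 2D space; its generate() output plays
    the role of observed data whose latents are known.
    """
    from .model import HierarchicalNBVAE, ModelConfig

    cfg = ModelConfig(dim_z=dim_z, dim_v=dim_v, seed=seed)
    model = HierarchicalNBVAE(cfg, [f"g{i}" for i in range(n_genes)])
    model.decoder_h.weight.data *= expression_contrast
    model.log_theta.data[:] = np.log(dispersion)
    return model


def lognormal_library_sizes(
    n: int, median: float = 5000.0, sigma: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Log-normal per-cell sequencing depths around a median."""
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(np.log(median), sigma, n))
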
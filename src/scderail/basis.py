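"""Probabilistic basis decomposition of gene patterns across conditions.

Each gene pattern (expression as a function of pseudotime, one function
per gene and condition) is modeled as a scale times a convex combination
of K shared temporal basis functions:

    pattern_{g,c}(t) ~ Normal( s_{g,c} * sum_k beta_{g,c,k} b_k(t), sigma^2 )

* the weights ``beta_{g,c}`` live on the simplex with a symmetric
  Dirichlet prior (concentration eta < 1 encourages sparse, dominant
  patterns),
* each basis ``b_k`` is a small neural network (1 -> 32 -> 32 -> 1,
  tanh) whose weight prior (centered normal, variance 1/fan-in)
  approximates a Gaussian-process prior in function space; bases are
  squashed to (0, 1] and max-normalized so the scale ``s`` is
  interpretable,
* the observation kernel is white noise, so the likelihood factorizes
  over grid points.

Comparing a gene between two conditions reduces to comparing its
decomposition: scale disruption |log s_1 - log s_2|, shape disruption
||beta_1 - beta_2||, and combined disruption ||log(s_1 beta_1) -
log(s_2 beta_2)||.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .autodiff import Adam, Parameter, Tensor, concat


# ---------------------------------------------------------------------------
# containers


@dataclass
class PatternMatrix:
    """Gene x condition x time grid of pattern values (shared grid)."""

    values: np.ndarray
    time_grid: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.time_grid = np.asarray(self.time_grid, float)
        if self.values.ndim != 3:
            raise ValueError("values must be (gene, condition, time)")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite pattern value at (gene, condition, time) = {tuple(bad)}")
        g, c, t = self.values.shape
        if (len(self.gene_ids), len(self.condition_ids), len(self.time_grid)) != (g, c, t):
            raise ValueError("id/grid lengths do not match values shape")

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, value_col: str = "value", n_grid: int = 100
    ) -> "PatternMatrix":
        """Build from long format (gene, condition, time, value), linearly
        resampling every series onto a shared uniform grid."""
        genes = sorted(df["gene"].astype(str).unique())
        conds = sorted(df["condition"].astype(str).unique())
        lo, hi = df["time"].min(), df["time"].max()
        grid = np.linspace(lo, hi, n_grid)
        values = np.empty((len(genes), len(conds), n_grid))
        for i, g in enumerate(genes):
            for j, c in enumerate(conds):
                sub = df[(df["gene"].astype(str) == g) & (df["condition"].astype(str) == c)]
                sub = sub.sort_values("time")
                if len(sub) == 0:
                    raise ValueError(f"no pattern for gene {g!r}, condition {c!r}")
                values[i, j] = np.interp(grid, sub["time"], sub[value_col])
        return cls(values, grid, genes, conds)

    def to_long(self, value_col: str = "value") -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.gene_ids):
            for j, c in enumerate(self.condition_ids):
                rows.append(
                    pd.DataFrame(
                        {
                            "gene": g,
                            "condition": c,
                            "time": self.time_grid,
                            value_col: self.values[i, j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass
class BasisConfig:
    """Hyperparameters of the decomposition.

    ``eta`` below 1 biases the weights toward sparse combinations of
    dominant patterns.
    """

    K: int = 5
    eta: float = 0.25
    hidden_width: int = 32
    noise_variance_init: float = 0.01
    n_steps: int = 3000
    learning_rate: float = 1e-2
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass
class BasisFit:
    """Fitted decomposition: K max-normalized bases on the grid, simplex
    weights and positive scales per (gene, condition), and the noise
    variance."""

    basis_values: np.ndarray  # K x T, each row max-normalized to 1
    weights: np.ndarray  # gene x condition x K, rows on the simplex
    scales: np.ndarray  # gene x condition, > 0
    noise_variance: float
    time_grid: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]
    loss_trace: list[float] = field(default_factory=list)

    def _locate(self, gene: str, condition: str) -> tuple[int, int]:
        try:
            return self.gene_ids.index(str(gene)), self.condition_ids.index(str(condition))
        except ValueError as exc:
            raise KeyError(f"unknown gene or condition: {gene!r}, {condition!r}") from exc


# ---------------------------------------------------------------------------
# basis networks


class _BasisNet:
    """1 -> W -> W -> 1 tanh network; evaluated on the whole grid."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.w1 = Parameter(rng.normal(0, 1.0, (1, width)))  # fan-in 1
        self.b1 = Parameter(rng.normal(0, 1.0, width))
        self.w2 = Parameter(rng.normal(0, np.sqrt(1.0 / width), (width, width)))
        self.b2 = Parameter(rng.normal(0, np.sqrt(1.0 / width), width))
        self.w3 = Parameter(rng.normal(0, np.sqrt(1.0 / width), (width, 1)))
        self.b3 = Parameter(rng.normal(0, np.sqrt(1.0 / width), 1))

    def __call__(self, t: Tensor) -> Tensor:
        h = (t @ self.w1 + self.b1).tanh()
        h = (h @ self.w2 + self.b2).tanh()
        return h @ self.w3 + self.b3

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def prior_penalty(self) -> Tensor:
        """Negative log of the centered-normal weight prior (var = 1/fan-in),
        up to constants."""
        width = self.w2.data.shape[0]
        total = (self.w1 * self.w1).sum() + (self.b1 * self.b1).sum()
        total = total + width * ((self.w2 * self.w2).sum() + (self.b2 * self.b2).sum())
        total = total + width * ((self.w3 * self.w3).sum() + (self.b3 * self.b3).sum())
        return 0.5 * total


def _normalized_basis(nets: list[_BasisNet], grid: np.ndarray) -> Tensor:
    """K x T basis tensor: sigmoid-squashed then divided by the row max,
    so values lie in (0, 1] and each row's max is exactly 1."""
    from .autodiff import concat

    t = Tensor(grid[:, None])
    rows = [net(t).sigmoid().transpose() for net in nets]  # each 1 x T
    b = concat(rows, axis=0)
    return b / b.max(axis=1, keepdims=True)


def sample_basis_prior(config: BasisConfig, seed: int = 0) -> np.ndarray:
    """Draw K basis functions from the function-space prior, evaluated on
    a uniform grid of length 100 on [0, 1] (use ``sample_basis_prior_on``
    for a custom grid)."""
    return sample_basis_prior_on(config, np.linspace(0, 1, 100), seed)


def sample_basis_prior_on(
    config: BasisConfig, grid: np.ndarray, seed: int = 0
) -> np.ndarray:
    grid = np.asarray(grid, float)
    if len(grid) < 2:
        raise ValueError("grid must have at least 2 points")
    rng = np.random.default_rng(seed)
    nets = [_BasisNet(config.hidden_width, rng) for _ in range(config.K)]
    return _normalized_basis(nets, grid).data.copy()


# ---------------------------------------------------------------------------
# Dirichlet density


def dirichlet_log_density(beta: np.ndarray, eta: float) -> float:
    """Log density of the symmetric Dirichlet(eta, ..., eta).

    Returns -inf (as a float, not an exception) when eta < 1 and some
    coordinate is exactly 0, where the density diverges or vanishes.
    """
    beta = np.asarray(beta, float)
    if eta <= 0:
        raise ValueError("eta must be positive")
    if np.any(beta < -1e-8) or abs(beta.sum() - 1.0) > 1e-8:
        raise ValueError("beta must lie on the probability simplex")
    k = len(beta)
    if np.any(beta <= 0):
        return float("-inf") if eta < 1 else (
            float(gammaln(k * eta) - k * gammaln(eta)) if eta == 1 else float("-inf")
        )
    log_b = float(gammaln(k * eta) - k * gammaln(eta))
    return log_b + float((eta - 1.0) * np.log(beta).sum())


# ---------------------------------------------------------------------------
# fitting


def fit_basis(patterns: PatternMatrix, config: BasisConfig | None = None) -> BasisFit:
    """Fit the decomposition by stochastic variational inference.

    The simplex weights carry a logistic-normal variational family:
    ``u ~ Normal(alpha, diag(sigma^2))`` in K-1 unconstrained
    dimensions, mapped to the simplex by a zero-padded softmax. The
    Dirichlet prior is pulled back through that transform (including
    its log-Jacobian, ``sum_k log beta_k``), which keeps the objective
    proper for eta < 1 — a point estimate would collapse weights onto
    the simplex boundary. Basis-network weights are point-estimated
    under their Gaussian prior; scales and the noise variance are
    log-parameterized point estimates. Returned weights are posterior
    means (Monte-Carlo over the fitted logistic-normal), so each vector
    sums to 1 up to float addition.
    """
    config = config or BasisConfig()
    G, C, T = patterns.values.shape
    if G < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(config.seed)
    # normalize the grid to [0, 1] for the basis networks
    grid = patterns.time_grid
    span = grid[-1] - grid[0] if grid[-1] > grid[0] else 1.0
    grid01 = (grid - grid[0]) / span
    nets = [_BasisNet(config.hidden_width, rng) for _ in range(config.K)]
    n_obs, K = G * C, config.K
    alpha = Parameter(rng.normal(0, 0.1, (n_obs, K - 1)))
    log_sigma_u = Parameter(np.full((n_obs, K - 1), -2.0))
    init_scale = np.log(np.maximum(patterns.values.max(axis=2).reshape(-1), 1e-3))
    log_s = Parameter(init_scale)
    log_var = Parameter(np.array([np.log(config.noise_variance_init)]))
    data = Tensor(patterns.values.reshape(n_obs, T))
    params = [p for net in nets for p in net.parameters()] + [
        alpha,
        log_sigma_u,
        log_s,
        log_var,
    ]
    opt = Adam(params, lr=config.learning_rate)
    eta = config.eta
    pad = Tensor(np.zeros((n_obs, 1)))
    trace = []
    for step in range(config.n_steps):
        b = _normalized_basis(nets, grid01)  # K x T
        eps = rng.standard_normal((n_obs, K - 1))
        u = alpha + log_sigma_u.exp() * Tensor(eps)
        log_beta = concat([u, pad], axis=1).log_softmax(axis=1)
        beta = log_beta.exp()
        recon = (beta @ b) * log_s.exp().reshape(n_obs, 1)
        var = log_var.exp()
        resid = data - recon
        nll = 0.5 * ((resid * resid) / var + var.log()).sum()
        # Dirichlet prior pulled back through the softmax transform:
        # (eta - 1) sum log beta + Jacobian sum log beta = eta sum log beta
        log_prior_u = eta * log_beta.sum()
        entropy = log_sigma_u.sum()
        net_prior = sum((net.prior_penalty() for net in nets), Tensor(0.0))
        loss = nll - log_prior_u - entropy + net_prior
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    b = _normalized_basis(nets, grid01).data
    # posterior mean of beta under the fitted logistic-normal
    draws = 512
    eps = rng.standard_normal((draws, n_obs, K - 1))
    u = alpha.data[None] + np.exp(log_sigma_u.data)[None] * eps
    u = np.concatenate([u, np.zeros((draws, n_obs, 1))], axis=2)
    u -= u.max(axis=2, keepdims=True)
    expu = np.exp(u)
    beta = (expu / expu.sum(axis=2, keepdims=True)).mean(axis=0)
    beta /= beta.sum(axis=1, keepdims=True)
    return BasisFit(
        basis_values=b,
        weights=beta.reshape(G, C, K),
        scales=np.exp(log_s.data).reshape(G, C),
        noise_variance=float(np.exp(log_var.data[0])),
        time_grid=grid.copy(),
        gene_ids=list(patterns.gene_ids),
        condition_ids=list(patterns.condition_ids),
        loss_trace=trace,
    )


def reconstruct_pattern(fit: BasisFit, gene: str, condition: str) -> np.ndarray:
    """s * (beta . basis): the fitted approximation of one pattern."""
    i, j = fit._locate(gene, condition)
    return fit.scales[i, j] * (fit.weights[i, j] @ fit.basis_values)


# ---------------------------------------------------------------------------
# disruption scores


def disruption_scores(
    fit: BasisFit,
    cond_pair: tuple[str, str],
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Scale, shape, and combined disruption per gene between two
    conditions.

    scale    = |log s_1 - log s_2|
    shape    = ||beta_1 - beta_2||_2
    combined = ||log(s_1 (beta_1 + eps)) - log(s_2 (beta_2 + eps))||_2

    All three are symmetric in the pair and zero when the decompositions
    coincide.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    c1, c2 = cond_pair
    j1 = fit.condition_ids.index(str(c1))
    j2 = fit.condition_ids.index(str(c2))
    s1, s2 = fit.scales[:, j1], fit.scales[:, j2]
    b1, b2 = fit.weights[:, j1, :], fit.weights[:, j2, :]
    scale = np.abs(np.log(s1) - np.log(s2))
    shape = np.linalg.norm(b1 - b2, axis=1)
    combined = np.linalg.norm(
        np.log(s1[:, None] * (b1 + epsilon)) - np.log(s2[:, None] * (b2 + epsilon)),
        axis=1,
    )
    return pd.DataFrame(
        {
            "gene": fit.gene_ids,
            "scale_disruption": scale,
            "shape_disruption": shape,
            "combined_disruption": combined,
        }
    )
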
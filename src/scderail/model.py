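"""Hierarchical negative-binomial VAE with a 2D visualization space.

The generative model stacks two latent levels over gene expression:

* ``v_i ~ Normal(0, I)`` — a 2D top-level representation of cell *i*
  whose plane is used directly for visualization,
* ``z_i ~ Normal(f_mean(v_i), f_var(v_i))`` — mid-dimensional latent
  factors (default 10), generated *conditionally* on ``v_i`` so they may
  be mutually correlated,
* ``x_{i,g} ~ NB(mu_{i,g} * l_i, theta_g)`` with
  ``mu_i = softmax(h(z_i))``, where ``l_i`` is the observed library size
  and ``theta_g`` a learned per-gene inverse dispersion
  (``var = mean + mean^2 / theta``).

``f`` is a one-hidden-layer network whose final affine output is split
into mean and variance halves; ``h`` is a single linear layer followed
by a softmax, keeping the map from latent factors to expression close to
interpretable. Inference is amortized stochastic variational inference
on a beta-weighted ELBO, with a ``q(z|x)`` encoder and a ``q(v|z,x)``
encoder, trained with Adam on minibatches.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import (
    Adam,
    Linear,
    MLP,
    Parameter,
    Tensor,
    concat,
    nb_log_prob_op,
)
from .data import CountMatrix

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-4


@dataclass
class ModelConfig:
    """Hyperparameters of the hierarchical VAE.

    ``beta`` down-weights the prior term on ``v`` in the ELBO (1 is the
    standard ELBO, 0 drops the prior); a low value leaves the 2D space
    mostly data-driven.
    """

    dim_z: int = 10
    dim_v: int = 2
    hidden_v_to_z: list[int] = field(default_factory=lambda: [64])
    hidden_x_to_z: list[int] = field(default_factory=lambda: [128])
    hidden_xz_to_v: list[int] = field(default_factory=lambda: [128])
    beta: float = 0.1
    batch_size: int = 64
    learning_rate: float = 5e-3
    max_epochs: int = 100
    early_stopping: bool = False
    patience: int = 5
    val_fraction: float = 0.1
    f_var_warmup_epochs: int = 50
    f_var_warmup_value: float = 0.05
    refine_decoder_steps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if self.dim_v <= 0 or self.dim_z <= 0:
            raise ValueError("latent dimensions must be positive")

    def validate_for_fit(self, n_genes: int):
        if not (self.dim_v < self.dim_z < n_genes):
            raise ValueError(
                f"need dim_v < dim_z < n_genes, got {self.dim_v}, "
                f"{self.dim_z}, {n_genes}"
            )


@dataclass
class Embedding:
    """Per-cell posterior means ``v`` (2D) and ``z``, plus the orthogonal
    transform currently applied to the raw ``v`` (identity if none)."""

    v: np.ndarray
    z: np.ndarray
    transform: np.ndarray
    cell_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"v{i + 1}": self.v[:, i] for i in range(self.v.shape[1])}
        cols.update({f"z{i + 1}": self.z[:, i] for i in range(self.z.shape[1])})
        return pd.DataFrame(cols, index=pd.Index(self.cell_ids, name="cell_id"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Embedding":
        vcols = sorted([c for c in df.columns if c.startswith("v")], key=lambda c: int(c[1:]))
        zcols = sorted([c for c in df.columns if c.startswith("z")], key=lambda c: int(c[1:]))
        return cls(
            v=df[vcols].to_numpy(float),
            z=df[zcols].to_numpy(float),
            transform=np.eye(len(vcols)),
            cell_ids=[str(i) for i in df.index],
        )


def nb_log_prob(x, mean, dispersion):
    """Log-pmf of the negative binomial, mean/dispersion parameterization.

    ``variance = mean + mean**2 / dispersion``; the Poisson limit is
    recovered as ``dispersion -> infinity``. Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    theta = np.asarray(dispersion, dtype=float)
    if np.any(x < 0) or np.any(np.abs(x - np.round(x)) > 1e-9):
        raise ValueError("x must be a non-negative integer")
    if np.any(mean <= 0) or np.any(theta <= 0):
        raise ValueError("mean and dispersion must be positive")
    from scipy.special import gammaln

    out = (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (np.log(theta) - np.log(theta + mean))
        + x * (np.log(mean) - np.log(theta + mean))
    )
    return out if out.ndim else float(out)


def _split_mean_var(out: Tensor, dim: int) -> tuple[Tensor, Tensor]:
    mean = out.slice((slice(None), slice(0, dim)))
    raw = out.slice((slice(None), slice(dim, 2 * dim)))
    var = raw.softplus() + _VAR_FLOOR
    return mean, var


def _normal_logpdf(x: Tensor, mean, var) -> Tensor:
    mean = mean if isinstance(mean, Tensor) else Tensor(mean)
    var = var if isinstance(var, Tensor) else Tensor(var)
    diff = x - mean
    return -0.5 * (diff * diff / var + var.log() + _LOG2PI)


def _cell_seed(cell_id: str, seed: int) -> int:
    return (zlib.crc32(str(cell_id).encode()) ^ (seed * 0x9E3779B1)) & 0x7FFFFFFF


class HierarchicalNBVAE:
    """The trained (or freshly initialized) generative model.

    Construct directly for simulation studies, or through :func:`fit`.
    """

    def __init__(self, config: ModelConfig, gene_ids: list[str]):
        self.config = config
        self.gene_ids = [str(g) for g in gene_ids]
        G = len(self.gene_ids)
        rng = np.random.default_rng(config.seed)
        c = config
        self.decoder_f = MLP(c.dim_v, list(c.hidden_v_to_z), 2 * c.dim_z, rng)
        self.decoder_h = Linear(c.dim_z, G, rng)
        self.encoder_z = MLP(G, list(c.hidden_x_to_z), 2 * c.dim_z, rng)
        self.encoder_v = MLP(G + c.dim_z, list(c.hidden_xz_to_v), 2 * c.dim_v, rng)
        # start all variance heads sharp (softplus^-1 of 0.05): training that
        # begins in the high-variance regime tends to stall in a plateau
        # where neither f nor q(v|z,x) organizes the 2D space
        sharp = float(np.log(np.expm1(0.05)))
        self.decoder_f.layers[-1].bias.data[c.dim_z :] = sharp
        self.encoder_z.layers[-1].bias.data[c.dim_z :] = sharp
        self.encoder_v.layers[-1].bias.data[c.dim_v :] = sharp
        self.log_theta = Parameter(np.zeros(G))
        self.training_log = pd.DataFrame()
        # during warm-up epochs p(z|v) uses this fixed variance, which keeps
        # the gradient pressure on encoder_v/decoder_f high while the 2D
        # space self-organizes; None outside warm-up
        self._f_var_clamp: float | None = None

    # -- plumbing -------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def dispersions(self) -> np.ndarray:
        return np.exp(self.log_theta.data)

    def parameters(self):
        return (
            self.decoder_f.parameters()
            + self.decoder_h.parameters()
            + self.encoder_z.parameters()
            + self.encoder_v.parameters()
            + [self.log_theta]
        )

    def _set_training(self, mode: bool):
        for net in (self.decoder_f, self.encoder_z, self.encoder_v):
            net.set_training(mode)

    # -- generative side ------------------------------------------------------
    def prior_z(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean and variance of p(z|v) from decoder f (eval mode)."""
        self._set_training(False)
        out = self.decoder_f(Tensor(np.atleast_2d(v)))
        mean, var = _split_mean_var(out, self.config.dim_z)
        return mean.data, var.data

    def expression_probs(self, z: np.ndarray) -> np.ndarray:
        """softmax(h(z)): normalized expression over genes, rows sum to 1."""
        logits = self.decoder_h(Tensor(np.atleast_2d(z)))
        return logits.softmax().data

    def generate(
        self,
        n_cells: int,
        library_sizes: np.ndarray | float,
        seed: int,
    ) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
        """Sample cells from the generative model.

        Returns the counts together with the latent ``v`` and ``z`` used,
        so simulation studies can score recovery against the truth.
        """
        if n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        lib = np.broadcast_to(np.asarray(library_sizes, float).ravel()
                              if np.ndim(library_sizes) else
                              np.full(n_cells, float(library_sizes)), (n_cells,)).copy()
        bad = np.flatnonzero(lib <= 0)
        if bad.size:
            raise ValueError(f"non-positive library size for cell index {bad[0]}")
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((n_cells, self.config.dim_v))
        f_mean, f_var = self.prior_z(v)
        z = f_mean + np.sqrt(f_var) * rng.standard_normal(f_mean.shape)
        mu = self.expression_probs(z)
        mean = mu * lib[:, None]
        theta = self.dispersions[None, :]
        # NB via gamma-Poisson mixture
        lam = rng.gamma(shape=np.broadcast_to(theta, mean.shape),
                        scale=mean / theta)
        counts = rng.poisson(lam).astype(np.int64)
        cm = CountMatrix(
            counts,
            [f"cell{i}" for i in range(n_cells)],
            self.gene_ids,
        )
        return cm, v, z

    # -- variational side -----------------------------------------------------
    def _encode_tensors(self, x: np.ndarray, eps_z: np.ndarray | None):
        """Shared forward pass of the two encoders.

        If ``eps_z`` is None, z is set to the posterior mean (used by
        encode()); otherwise z is the reparameterized sample.
        """
        x_enc = Tensor(np.log1p(x))
        qz = self.encoder_z(x_enc)
        qz_mean, qz_var = _split_mean_var(qz, self.config.dim_z)
        if eps_z is None:
            z = qz_mean
        else:
            z = qz_mean + qz_var.sqrt() * Tensor(eps_z)
        qv = self.encoder_v(concat([x_enc, z], axis=1))
        qv_mean, qv_var = _split_mean_var(qv, self.config.dim_v)
        return qz_mean, qz_var, z, qv_mean, qv_var

    def _elbo_cells(
        self,
        x: np.ndarray,
        lib: np.ndarray,
        eps_z: np.ndarray,
        eps_v: np.ndarray,
    ) -> Tensor:
        """Reparameterized single-sample ELBO per cell (vector of length N).

        z is sampled first from q(z|x), then v from q(v|z,x), mirroring
        the factorization q(v,z|x) = q(v|z,x) q(z|x).
        """
        qz_mean, qz_var, z, qv_mean, qv_var = self._encode_tensors(x, eps_z)
        v = qv_mean + qv_var.sqrt() * Tensor(eps_v)
        # likelihood
        logits = self.decoder_h(z)
        log_mu = logits.log_softmax() + Tensor(np.log(lib)[:, None])
        log_px = nb_log_prob_op(x, log_mu, self.log_theta).sum(axis=1)
        # p(z|v) from decoder f
        f_out = self.decoder_f(v)
        f_mean, f_var = _split_mean_var(f_out, self.config.dim_z)
        if self._f_var_clamp is not None:
            f_var = Tensor(np.full((1, self.config.dim_z), self._f_var_clamp))
        log_pz = _normal_logpdf(z, f_mean, f_var).sum(axis=1)
        log_qz = _normal_logpdf(z, qz_mean, qz_var).sum(axis=1)
        log_pv = _normal_logpdf(v, Tensor(0.0), Tensor(1.0)).sum(axis=1)
        log_qv = _normal_logpdf(v, qv_mean, qv_var).sum(axis=1)
        beta = self.config.beta
        return log_px + log_pz - log_qz + beta * (log_pv - log_qv)

    def elbo(
        self,
        batch: CountMatrix,
        n_mc_samples: int = 1,
        seed: int = 0,
    ) -> float:
        """Monte-Carlo ELBO estimate of the batch (sum over cells).

        Per-cell noise is seeded from the cell id, so the estimate is
        invariant to cell order and additive under batch concatenation.
        """
        if n_mc_samples < 1:
            raise ValueError("n_mc_samples must be >= 1")
        if batch.n_cells == 0:
            raise ValueError("batch is empty")
        self._set_training(False)
        x = batch.dense().astype(float)
        lib = batch.library_sizes
        c = self.config
        n = batch.n_cells
        # per-cell noise streams keyed by cell id
        rngs = [np.random.default_rng(_cell_seed(cid, seed)) for cid in batch.cell_ids]
        eps_z = np.stack([r.standard_normal((n_mc_samples, c.dim_z)) for r in rngs], axis=1)
        eps_v = np.stack([r.standard_normal((n_mc_samples, c.dim_v)) for r in rngs], axis=1)
        total = 0.0
        # tile cells across MC samples in chunks to bound memory
        chunk = max(1, 20000 // max(n, 1))
        for start in range(0, n_mc_samples, chunk):
            m = min(chunk, n_mc_samples - start)
            x_t = np.tile(x, (m, 1))
            lib_t = np.tile(lib, m)
            ez = eps_z[start : start + m].reshape(m * n, c.dim_z)
            ev = eps_v[start : start + m].reshape(m * n, c.dim_v)
            total += float(self._elbo_cells(x_t, lib_t, ez, ev).sum().data)
        return total / n_mc_samples

    def encode(self, data: CountMatrix) -> Embedding:
        """Posterior-mean embedding: z = encoder_z mean, v = encoder_v mean."""
        if list(data.gene_ids) != self.gene_ids:
            extra = set(data.gene_ids) - set(self.gene_ids)
            missing = set(self.gene_ids) - set(data.gene_ids)
            raise ValueError(
                "gene set mismatch (order-sensitive); "
                f"unexpected={sorted(extra)[:5]}, missing={sorted(missing)[:5]}"
            )
        self._set_training(False)
        _, _, z, qv_mean, _ = self._encode_tensors(data.dense().astype(float), None)
        return Embedding(
            v=qv_mean.data.copy(),
            z=z.data.copy(),
            transform=np.eye(self.config.dim_v),
            cell_ids=list(data.cell_ids),
        )

    def decode(
        self, v_points: np.ndarray, library_size: float = 1.0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Expected expression at 2D points: z = f_mean(v), mu = softmax(h(z)).

        Returns ``(mu * library_size, z)``; each mu row sums to 1 before
        scaling.
        """
        v_points = np.atleast_2d(np.asarray(v_points, float))
        z, _ = self.prior_z(v_points)
        mu = self.expression_probs(z)
        return mu * float(library_size), z

    def decode_with_uncertainty(
        self,
        v_points: np.ndarray,
        n_samples: int = 100,
        seed: int = 0,
        library_size: float = 1.0,
    ) -> dict[str, np.ndarray]:
        """Quantile bands of mu over z ~ Normal(f_mean(v), f_var(v)).

        Samples ``n_samples`` latent draws per point (100 by default) and
        returns the elementwise 25th/50th/75th percentiles of the decoded
        expression, scaled by ``library_size``.
        """
        if n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        v_points = np.atleast_2d(np.asarray(v_points, float))
        f_mean, f_var = self.prior_z(v_points)
        rng = np.random.default_rng(seed)
        draws = np.empty((n_samples, v_points.shape[0], self.n_genes))
        for m in range(n_samples):
            z_m = f_mean + np.sqrt(f_var) * rng.standard_normal(f_mean.shape)
            draws[m] = self.expression_probs(z_m)
        q25, q50, q75 = np.percentile(draws, [25, 50, 75], axis=0)
        s = float(library_size)
        return {"q25": q25 * s, "q50": q50 * s, "q75": q75 * s}

    # -- training -------------------------------------------------------------
    def _train(self, data: CountMatrix):
        c = self.config
        lib = data.library_sizes
        zero = np.flatnonzero(lib == 0)
        if zero.size:
            ids = [data.cell_ids[i] for i in zero[:10]]
            raise ValueError(f"cells with zero library size: {ids}")
        c.validate_for_fit(data.n_genes)
        x_all = data.dense().astype(float)
        rng = np.random.default_rng(c.seed)
        n = data.n_cells
        idx = rng.permutation(n)
        if c.early_stopping:
            n_val = max(1, int(round(c.val_fraction * n)))
            val_idx, train_idx = idx[:n_val], idx[n_val:]
        else:
            val_idx, train_idx = np.array([], int), idx
        val_batch = data.subset_cells(val_idx) if len(val_idx) else None
        opt = Adam(self.parameters(), lr=c.learning_rate)
        log_rows = []
        best_val, best_state, patience_left = -np.inf, None, c.patience
        for epoch in range(c.max_epochs):
            self._f_var_clamp = (
                c.f_var_warmup_value if epoch < c.f_var_warmup_epochs else None
            )
            self._set_training(True)
            order = rng.permutation(train_idx)
            losses = []
            for start in range(0, len(order), c.batch_size):
                b = order[start : start + c.batch_size]
                if len(b) < 2:
                    continue  # batch norm needs at least 2 cells
                x = x_all[b]
                eps_z = rng.standard_normal((len(b), c.dim_z))
                eps_v = rng.standard_normal((len(b), c.dim_v))
                elbo = self._elbo_cells(x, lib[b], eps_z, eps_v)
                loss = -(elbo.mean())
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if val_batch is not None:
                val_elbo = self.elbo(val_batch, n_mc_samples=1, seed=c.seed) / len(
                    val_idx
                )
                row["val_elbo"] = val_elbo
                if val_elbo > best_val + 1e-9:
                    best_val, patience_left = val_elbo, c.patience
                    best_state = [p.data.copy() for p in self.parameters()]
                else:
                    patience_left -= 1
            log_rows.append(row)
            if val_batch is not None and patience_left <= 0:
                break
        self._f_var_clamp = None
        if best_state is not None:
            for p, s in zip(self.parameters(), best_state):
                p.data = s
        self.training_log = pd.DataFrame(log_rows)
        self._set_training(False)
        if c.refine_decoder_steps > 0:
            self._refine_decoder(x_all, rng)
        return self

    def _refine_decoder(self, x_all: np.ndarray, rng: np.random.Generator):
        """Tighten decoder f on posterior means after SVI.

        Amortized SVI trains f against sampled (v, z) pairs; decoding a
        trajectory, however, evaluates f at posterior *means*. This stage
        closes that gap by a short Gaussian-likelihood regression of the
        per-cell posterior-mean z on the posterior-mean v, re-estimating
        f's variance head from the residuals. Encoders are untouched.
        """
        c = self.config
        _, _, z, qv_mean, _ = self._encode_tensors(x_all, None)
        V, Z = qv_mean.data, z.data
        self.decoder_f.set_training(True)
        opt = Adam(self.decoder_f.parameters(), lr=c.learning_rate)
        n = len(V)
        for _ in range(c.refine_decoder_steps):
            b = rng.integers(0, n, min(c.batch_size, n))
            out = self.decoder_f(Tensor(V[b]))
            f_mean, f_var = _split_mean_var(out, c.dim_z)
            loss = -(_normal_logpdf(Tensor(Z[b]), f_mean, f_var).mean())
            opt.zero_grad()
            loss.backward()
            opt.step()
        self.decoder_f.set_training(False)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path):
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"param_{i}"] = p.data
        bn_i = 0
        for net in (self.decoder_f, self.encoder_z, self.encoder_v):
            for layer in net.layers:
                if hasattr(layer, "running_mean"):
                    arrays[f"bn_mean_{bn_i}"] = layer.running_mean
                    arrays[f"bn_var_{bn_i}"] = layer.running_var
                    bn_i += 1
        np.savez(path / "params.npz", **arrays)
        (path / "config.json").write_text(json.dumps(asdict(self.config), indent=2))
        (path / "genes.txt").write_text("\n".join(self.gene_ids) + "\n")
        self.training_log.to_csv(path / "training_log.csv", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "HierarchicalNBVAE":
        path = Path(path)
        cfg = ModelConfig(**json.loads((path / "config.json").read_text()))
        genes = (path / "genes.txt").read_text().splitlines()
        model = cls(cfg, genes)
        arrays = np.load(path / "params.npz")
        for i, p in enumerate(model.parameters()):
            p.data = arrays[f"param_{i}"].copy()
        bn_i = 0
        for net in (model.decoder_f, model.encoder_z, model.encoder_v):
            for layer in net.layers:
                if hasattr(layer, "running_mean"):
                    layer.running_mean = arrays[f"bn_mean_{bn_i}"].copy()
                    layer.running_var = arrays[f"bn_var_{bn_i}"].copy()
                    bn_i += 1
        log_path = path / "training_log.csv"
        if log_path.exists() and log_path.stat().st_size > 1:
            try:
                model.training_log = pd.read_csv(log_path)
            except pd.errors.EmptyDataError:
                pass
        return model


def fit(data: CountMatrix, config: ModelConfig | None = None) -> HierarchicalNBVAE:
    """Fit the hierarchical VAE to raw counts by minibatch SVI."""
    config = config or ModelConfig()
    model = HierarchicalNBVAE(config, data.gene_ids)
    return model._train(data)


def fit_flat_nb_vae(
    data: CountMatrix,
    dim_z: int = 10,
    hidden: int = 128,
    batch_size: int = 64,
    learning_rate: float = 5e-3,
    max_epochs: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Ablation: a standard NB VAE without the 2D top level.

    Same building blocks (one-hidden-layer encoder, linear softmax
    decoder, per-gene dispersion) but with an isotropic standard-normal
    prior directly on z. Returns the posterior-mean z matrix; used as
    the "no top space" baseline in embedding benchmarks.
    """
    G = data.n_genes
    rng = np.random.default_rng(seed)
    enc = MLP(G, [hidden], 2 * dim_z, rng)
    enc.layers[-1].bias.data[dim_z:] = float(np.log(np.expm1(0.05)))
    dec = Linear(dim_z, G, rng)
    log_theta = Parameter(np.zeros(G))
    params = enc.parameters() + dec.parameters() + [log_theta]
    opt = Adam(params, lr=learning_rate)
    x_all = data.dense().astype(float)
    lib = data.library_sizes
    n = data.n_cells
    for _ in range(max_epochs):
        enc.set_training(True)
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            b = order[start : start + batch_size]
            if len(b) < 2:
                continue
            x = x_all[b]
            out = enc(Tensor(np.log1p(x)))
            q_mean, q_var = _split_mean_var(out, dim_z)
            z = q_mean + q_var.sqrt() * Tensor(rng.standard_normal((len(b), dim_z)))
            log_mu = dec(z).log_softmax() + Tensor(np.log(lib[b])[:, None])
            log_px = nb_log_prob_op(x, log_mu, log_theta).sum(axis=1)
            log_pz = _normal_logpdf(z, Tensor(0.0), Tensor(1.0)).sum(axis=1)
            log_qz = _normal_logpdf(z, q_mean, q_var).sum(axis=1)
            loss = -((log_px + log_pz - log_qz).mean())
            opt.zero_grad()
            loss.backward()
            opt.step()
    enc.set_training(False)
    out = enc(Tensor(np.log1p(x_all)))
    q_mean, _ = _split_mean_var(out, dim_z)
    return q_mean.data.copy()


# ---------------------------------------------------------------------------
# post-hoc alignment of the 2D space


def encode_order(values, order: list[str]) -> np.ndarray:
    """Integer-rank encoding of a categorical column given an ordering."""
    lookup = {str(label): i for i, label in enumerate(order)}
    codes = np.array([lookup.get(str(val), np.nan) for val in values], float)
    if np.isnan(codes).any():
        missing = sorted({str(v) for v in values} - set(lookup))
        raise ValueError(f"labels without a position in the order: {missing[:5]}")
    return codes


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def rotate_space(
    embedding: Embedding,
    axis_targets: list[tuple[np.ndarray, int]],
    n_angles: int = 100,
) -> Embedding:
    """Search 100 rotations x 4 axis flips for the orthogonal transform
    that best correlates each integer-encoded label with its target axis.

    ``axis_targets`` is a list of ``(codes, axis_index)`` pairs; codes
    are per-cell numeric ranks (see :func:`encode_order`). Distances in
    ``v`` are untouched — the transform is orthogonal by construction.
    """
    if embedding.v.shape[1] != 2:
        raise ValueError("rotation search is defined for 2D embeddings")
    for codes, axis in axis_targets:
        if len(codes) != embedding.v.shape[0]:
            raise ValueError("label vector length does not match cell count")
        if axis not in (0, 1):
            raise ValueError("target axis must be 0 or 1")
    best_score, best_T = -np.inf, np.eye(2)
    angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    for angle in angles:
        ca, sa = np.cos(angle), np.sin(angle)
        R = np.array([[ca, -sa], [sa, ca]])
        for f1 in (1.0, -1.0):
            for f2 in (1.0, -1.0):
                T = R @ np.diag([f1, f2])
                v_rot = embedding.v @ T.T
                score = sum(
                    _safe_pearson(np.asarray(codes, float), v_rot[:, axis])
                    for codes, axis in axis_targets
                )
                if score > best_score + 1e-12:
                    best_score, best_T = score, T
    return Embedding(
        v=embedding.v @ best_T.T,
        z=embedding.z.copy(),
        transform=best_T @ embedding.transform,
        cell_ids=list(embedding.cell_ids),
    )
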
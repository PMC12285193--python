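"""Tests of the hierarchical NB VAE: likelihood, generation, ELBO,
inference, decoding and rotation."""

import numpy as np
import pytest
import scipy.stats as st

from scderail import (
    CountMatrix,
    Embedding,
    ModelConfig,
    fit,
    nb_log_prob,
    rotate_space,
    synthetic_model,
)
from scderail.model import HierarchicalNBVAE


# ---------------------------------------------------------------------------
# negative binomial


class TestNBLogProb:
    def test_closed_form_at_zero(self):
        m, theta = 4.7, 2.3
        expected = theta * (np.log(theta) - np.log(theta + m))
        assert nb_log_prob(0, m, theta) == pytest.approx(expected, abs=1e-12)

    def test_normalizes_over_truncated_support(self):
        total = sum(np.exp(nb_log_prob(x, 3.0, 2.0)) for x in range(501))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_poisson_limit(self):
        assert nb_log_prob(2, 3.0, 1e8) == pytest.approx(
            st.poisson.logpmf(2, 3.0), abs=1e-4
        )

    def test_matches_scipy_nbinom(self):
        # independent parameterization oracle: n=theta, p=theta/(theta+mean)
        for x, mean, theta in [(0, 1.0, 5.0), (7, 3.5, 0.7), (40, 20.0, 2.0)]:
            expected = st.nbinom.logpmf(x, theta, theta / (theta + mean))
            assert nb_log_prob(x, mean, theta) == pytest.approx(expected, rel=1e-10)

    def test_variance_formula_mean_dispersion(self):
        # var = mean + mean^2/theta under this parameterization
        mean, theta = 6.0, 3.0
        xs = np.arange(0, 2000)
        pmf = np.exp(nb_log_prob(xs, mean, theta))
        assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
        assert (pmf * xs).sum() == pytest.approx(mean, abs=1e-8)
        var = (pmf * xs**2).sum() - mean**2
        assert var == pytest.approx(mean + mean**2 / theta, rel=1e-8)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            nb_log_prob(-1, 1.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_prob(1.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_prob(1, -2.0, 1.0)


# ---------------------------------------------------------------------------
# generation


class TestGenerate:
    def test_poisson_limit_dispersion(self):
        model = synthetic_model(n_genes=20, seed=0, dispersion=1e8)
        # constant decoder: mu identical for every cell, isolating the
        # count noise from latent variation
        model.decoder_h.weight.data[:] = 0.0
        data, _, _ = model.generate(4000, 1000.0, seed=1)
        x = data.dense().astype(float)
        ratio = x.var(axis=0) / np.maximum(x.mean(axis=0), 1e-9)
        # Poisson limit: variance/mean ratio near 1 for expressed genes
        expressed = x.mean(axis=0) > 1
        assert np.abs(ratio[expressed] - 1).max() < 0.2

    def test_seeded_determinism(self):
        model = synthetic_model(n_genes=15, seed=3)
        a, va, za = model.generate(50, 500.0, seed=9)
        b, vb, zb = model.generate(50, 500.0, seed=9)
        assert np.array_equal(a.dense(), b.dense())
        assert np.array_equal(va, vb) and np.array_equal(za, zb)

    def test_monte_carlo_moments_match_nb(self):
        """50k draws from one (mean, dispersion) pair reproduce the
        closed-form NB mean and variance within sampling error."""
        mean, theta, n = 8.0, 4.0, 50_000
        rng = np.random.default_rng(12)
        lam = rng.gamma(shape=theta, scale=mean / theta, size=n)
        x = rng.poisson(lam)  # same gamma-Poisson scheme as generate()
        true_var = mean + mean**2 / theta
        se_mean = np.sqrt(true_var / n)
        assert abs(x.mean() - mean) < 3 * se_mean
        # variance of the sample variance via the fourth moment
        m4 = ((x - x.mean()) ** 4).mean()
        se_var = np.sqrt((m4 - true_var**2) / n)
        assert abs(x.var() - true_var) < 4 * se_var

    def test_rejects_nonpositive_library(self):
        model = synthetic_model(n_genes=5, seed=0)
        with pytest.raises(ValueError, match="index 1"):
            model.generate(3, np.array([10.0, 0.0, 5.0]), seed=0)


# ---------------------------------------------------------------------------
# ELBO


def _random_batch(model, n, seed, prefix="c"):
    data, _, _ = model.generate(n, 300.0, seed=seed)
    return CountMatrix(
        data.dense(), [f"{prefix}{i}" for i in range(n)], data.gene_ids
    )


class TestElbo:
    def test_invariant_to_cell_order(self, tiny_model):
        batch = _random_batch(tiny_model, 6, seed=4)
        perm = np.array([3, 1, 5, 0, 2, 4])
        shuffled = batch.subset_cells(perm)
        a = tiny_model.elbo(batch, n_mc_samples=3, seed=0)
        b = tiny_model.elbo(shuffled, n_mc_samples=3, seed=0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_additive_over_cells(self, tiny_model):
        batch = _random_batch(tiny_model, 6, seed=4)
        first = batch.subset_cells(np.arange(3))
        second = batch.subset_cells(np.arange(3, 6))
        whole = tiny_model.elbo(batch, n_mc_samples=2, seed=1)
        parts = tiny_model.elbo(first, n_mc_samples=2, seed=1) + tiny_model.elbo(
            second, n_mc_samples=2, seed=1
        )
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_identical_cells_double_the_estimate(self, tiny_model):
        """Two batches holding the same cells (same ids, same counts)
        contribute identically, so their union-by-sum doubles the value."""
        batch = _random_batch(tiny_model, 3, seed=4)
        copy = CountMatrix(batch.dense(), batch.cell_ids, batch.gene_ids)
        one = tiny_model.elbo(batch, n_mc_samples=2, seed=7)
        two = one + tiny_model.elbo(copy, n_mc_samples=2, seed=7)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_rejects_bad_mc_count(self, tiny_model):
        batch = _random_batch(tiny_model, 3, seed=4)
        with pytest.raises(ValueError):
            tiny_model.elbo(batch, n_mc_samples=0)

    def test_lower_bounds_importance_sampled_evidence(self, tiny_model):
        """At beta = 1 the MC ELBO must sit below the log marginal
        likelihood, estimated by importance sampling from the prior."""
        model = tiny_model
        batch = _random_batch(model, 3, seed=4)
        elbo = model.elbo(batch, n_mc_samples=50_000, seed=0)

        rng = np.random.default_rng(99)
        M = 200_000
        x = batch.dense().astype(float)
        lib = batch.library_sizes
        v = rng.standard_normal((M, model.config.dim_v))
        f_mean, f_var = model.prior_z(v)
        z = f_mean + np.sqrt(f_var) * rng.standard_normal(f_mean.shape)
        mu = model.expression_probs(z)
        theta = model.dispersions
        log_evidence = 0.0
        se_sq = 0.0
        for i in range(batch.n_cells):
            logw = nb_log_prob(
                np.broadcast_to(x[i], mu.shape), mu * lib[i], theta
            ).sum(axis=1)
            m = logw.max()
            w = np.exp(logw - m)
            log_evidence += m + np.log(w.mean())
            se_sq += w.std() ** 2 / (w.mean() ** 2 * M)
        margin = 3 * np.sqrt(se_sq)
        assert np.isfinite(elbo)
        assert elbo <= log_evidence + margin


# ---------------------------------------------------------------------------
# fit / encode / decode


class TestFit:
    def test_training_reduces_loss(self, recovery):
        log = recovery["model"].training_log
        assert log.train_loss.iloc[-3:].mean() < log.train_loss.iloc[0]

    def test_seeded_determinism(self):
        truth = synthetic_model(n_genes=30, seed=1)
        data, _, _ = truth.generate(200, 800.0, seed=2)
        cfg = dict(seed=5, max_epochs=3, f_var_warmup_epochs=1, refine_decoder_steps=10)
        m1 = fit(data, ModelConfig(**cfg))
        m2 = fit(data, ModelConfig(**cfg))
        assert m1.training_log.equals(m2.training_log)
        emb1, emb2 = m1.encode(data), m2.encode(data)
        np.testing.assert_array_equal(emb1.v, emb2.v)
        np.testing.assert_array_equal(emb1.z, emb2.z)

    def test_rejects_zero_library_cells(self):
        truth = synthetic_model(n_genes=10, seed=1)
        data, _, _ = truth.generate(20, 300.0, seed=2)
        counts = data.dense()
        counts[7] = 0
        bad = CountMatrix(counts, data.cell_ids, data.gene_ids)
        with pytest.raises(ValueError, match="cell7"):
            fit(bad, ModelConfig(max_epochs=1))

    def test_dimension_contract_at_fit_time(self):
        truth = synthetic_model(n_genes=5, seed=1)
        data, _, _ = truth.generate(30, 300.0, seed=2)
        with pytest.raises(ValueError, match="dim_v < dim_z"):
            fit(data, ModelConfig(dim_z=10, dim_v=2, max_epochs=1))

    def test_recovers_v_up_to_linear_alignment(self, recovery):
        """Canonical correlation between inferred and generating v."""
        from sklearn.cross_decomposition import CCA

        emb = recovery["model"].encode(recovery["train"])
        v_true = recovery["v_true"][:2000]
        a, b = CCA(n_components=2).fit_transform(emb.v, v_true)
        ccs = [abs(np.corrcoef(a[:, i], b[:, i])[0, 1]) for i in range(2)]
        assert min(ccs) > 0.8

    def test_reconstructs_expression_on_held_out_cells(self, recovery):
        """Pooled Pearson of log-scaled expected expression (decode at
        the encoded v) against the generating model's truth."""
        model = recovery["model"]
        emb = model.encode(recovery["held"])
        mu_hat, _ = model.decode(emb.v)
        mu_true = recovery["mu_true"][2000:]
        lm = np.log1p(mu_hat * 5000)
        lt = np.log1p(mu_true * 5000)
        pooled = np.corrcoef(lm.ravel(), lt.ravel())[0, 1]
        assert pooled > 0.9

    def test_decode_roundtrip_per_cell(self, recovery):
        """Decode at each held-out cell's encoded v correlates with that
        cell's own normalized counts (log scale, high-count cells)."""
        model = recovery["model"]
        held = recovery["held"]
        emb = model.encode(held)
        mu_hat, _ = model.decode(emb.v)
        xn = held.dense() / held.library_sizes[:, None]
        top = np.argsort(held.library_sizes)[-100:]
        rs = [
            np.corrcoef(np.log1p(mu_hat[i] * 5000), np.log1p(xn[i] * 5000))[0, 1]
            for i in top
        ]
        assert np.mean(rs) > 0.8

    def test_v_axis_beats_random_projection(self, recovery):
        """The best-aligned v axis tracks the first generating coordinate
        better than random linear projections of the expression."""
        from scipy.stats import spearmanr

        emb = recovery["model"].encode(recovery["train"])
        t = recovery["v_true"][:2000, 0]
        ours = max(
            abs(spearmanr(emb.v[:, i], t).statistic) for i in range(2)
        )
        xn = np.log1p(recovery["train"].dense())
        rng = np.random.default_rng(0)
        null = max(
            abs(spearmanr(xn @ rng.standard_normal(xn.shape[1]), t).statistic)
            for _ in range(20)
        )
        assert ours > null


class TestEncodeDecode:
    def test_duplicated_cells_get_identical_rows(self):
        model = synthetic_model(n_genes=12, seed=4)
        data, _, _ = model.generate(5, 400.0, seed=5)
        x = data.dense()
        x[3] = x[0]
        dup = CountMatrix(x, data.cell_ids, data.gene_ids)
        emb = model.encode(dup)
        np.testing.assert_array_equal(emb.v[0], emb.v[3])
        np.testing.assert_array_equal(emb.z[0], emb.z[3])

    def test_embedding_shapes_under_default_config(self, recovery):
        emb = recovery["model"].encode(recovery["held"])
        assert emb.v.shape == (500, 2)
        assert emb.z.shape == (500, 10)

    def test_encode_rejects_gene_mismatch(self):
        model = synthetic_model(n_genes=6, seed=4)
        data, _, _ = model.generate(4, 300.0, seed=5)
        renamed = CountMatrix(
            data.dense(), data.cell_ids, [f"x{i}" for i in range(6)]
        )
        with pytest.raises(ValueError, match="gene set mismatch"):
            model.encode(renamed)

    def test_decode_rows_sum_to_one(self):
        model = synthetic_model(n_genes=40, seed=6)
        v = np.random.default_rng(0).normal(size=(17, 2))
        mu, z = model.decode(v, library_size=1.0)
        np.testing.assert_allclose(mu.sum(axis=1), 1.0, atol=1e-6)
        assert z.shape == (17, 10)

    def test_decode_scales_linearly_with_library_size(self):
        model = synthetic_model(n_genes=10, seed=6)
        v = np.random.default_rng(1).normal(size=(4, 2))
        a, _ = model.decode(v, library_size=100.0)
        b, _ = model.decode(v, library_size=200.0)
        np.testing.assert_allclose(b, 2 * a, rtol=1e-12)

    def test_uncertainty_band_ordering(self):
        model = synthetic_model(n_genes=25, seed=8)
        v = np.random.default_rng(2).normal(size=(6, 2))
        bands = model.decode_with_uncertainty(v, n_samples=50, seed=3)
        assert np.all(bands["q25"] <= bands["q50"] + 1e-15)
        assert np.all(bands["q50"] <= bands["q75"] + 1e-15)

    def test_uncertainty_collapses_with_zero_variance(self):
        model = synthetic_model(n_genes=25, seed=8)
        # force the variance head of f far negative: var hits its floor
        model.decoder_f.layers[-1].weight.data[:, model.config.dim_z :] = 0.0
        model.decoder_f.layers[-1].bias.data[model.config.dim_z :] = -40.0
        v = np.random.default_rng(2).normal(size=(4, 2))
        mu, _ = model.decode(v)
        bands = model.decode_with_uncertainty(v, n_samples=100, seed=3)
        # the variance floor (1e-4) leaves a residual spread of a few
        # percent; the bands must collapse to that level
        for q in ("q25", "q50", "q75"):
            np.testing.assert_allclose(bands[q], mu, rtol=6e-2, atol=1e-6)
        iqr = bands["q75"] - bands["q25"]
        assert np.median(iqr / mu) < 0.05

    def test_uncertainty_deterministic_under_seed(self):
        model = synthetic_model(n_genes=10, seed=8)
        v = np.random.default_rng(4).normal(size=(3, 2))
        a = model.decode_with_uncertainty(v, n_samples=100, seed=11)
        b = model.decode_with_uncertainty(v, n_samples=100, seed=11)
        for q in a:
            np.testing.assert_array_equal(a[q], b[q])


# ---------------------------------------------------------------------------
# rotation


def _grid_oracle(v, codes, axis, n_angles=100):
    """Independent exhaustive search over the same angle/flip grid."""
    best, best_t = -np.inf, None
    for angle in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        for f1 in (1, -1):
            for f2 in (1, -1):
                T = R @ np.diag([f1, f2])
                w = (v @ T.T)[:, axis]
                if np.std(w) == 0:
                    continue
                r = np.corrcoef(codes, w)[0, 1]
                if r > best:
                    best, best_t = r, T
    return best, best_t


class TestRotateSpace:
    def test_identity_when_already_aligned(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(300, 2))
        codes = v[:, 1] + rng.normal(0, 0.01, 300)
        emb = Embedding(v, np.zeros((300, 3)), np.eye(2), [str(i) for i in range(300)])
        rotated = rotate_space(emb, [(codes, 1)])
        before = np.corrcoef(codes, v[:, 1])[0, 1]
        after = np.corrcoef(codes, rotated.v[:, 1])[0, 1]
        assert after >= before - 1e-9

    def test_rotation_preserves_pairwise_distances(self):
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(1)
        v = rng.normal(size=(100, 2))
        codes = rng.normal(size=100)
        emb = Embedding(v, np.zeros((100, 3)), np.eye(2), [str(i) for i in range(100)])
        rotated = rotate_space(emb, [(codes, 0)])
        assert np.abs(pdist(v) - pdist(rotated.v)).max() < 1e-6
        T = rotated.transform
        np.testing.assert_allclose(T.T @ T, np.eye(2), atol=1e-12)

    def test_matches_brute_force_grid_on_diagonal_labels(self):
        """Labels increasing along (1,1)/sqrt(2): the chosen transform
        achieves the same maximum as an independent grid search."""
        rng = np.random.default_rng(2)
        v = rng.normal(size=(500, 2))
        codes = (v @ np.array([1.0, 1.0])) / np.sqrt(2) + rng.normal(0, 0.05, 500)
        emb = Embedding(v, np.zeros((500, 3)), np.eye(2), [str(i) for i in range(500)])
        rotated = rotate_space(emb, [(codes, 0)])
        achieved = np.corrcoef(codes, rotated.v[:, 0])[0, 1]
        oracle_best, oracle_T = _grid_oracle(v, codes, 0)
        assert achieved == pytest.approx(oracle_best, abs=1e-12)
        # the rotation angle is within one grid step of the oracle's
        ours_angle = np.arctan2(rotated.transform[1, 0], rotated.transform[0, 0])
        oracle_angle = np.arctan2(oracle_T[1, 0], oracle_T[0, 0])
        step = 2 * np.pi / 100
        diff = np.abs((ours_angle - oracle_angle + np.pi) % (2 * np.pi) - np.pi)
        assert diff < step + 1e-9

    def test_rejects_bad_targets(self):
        emb = Embedding(
            np.zeros((5, 2)), np.zeros((5, 3)), np.eye(2), [str(i) for i in range(5)]
        )
        with pytest.raises(ValueError):
            rotate_space(emb, [(np.zeros(4), 0)])
        with pytest.raises(ValueError):
            rotate_space(emb, [(np.zeros(5), 3)])
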
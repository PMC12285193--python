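"""Shared fixtures: all data is generated programmatically at test time.

The two expensive fixtures (a parameter-recovery study and a trained
fork simulation) are session-scoped so every test that needs a trained
model reuses the same fit.
"""

from __future__ import annotations

import numpy as np
import pytest

from scderail import (
    ModelConfig,
    build_cluster_graph,
    cluster_latent,
    expression_to_counts,
    fit,
    interpolate_path,
    lognormal_library_sizes,
    map_to_expression,
    median_normalize_log1p,
    simulate_states,
    simulated_count_matrix,
    synthetic_model,
)


@pytest.fixture(scope="session")
def recovery():
    """Ground-truth model, self-generated data, and a fitted model.

    The study condition: a known generative model over 200 genes with
    realistic dispersion, 2500 cells at log-normal depth (median 5000);
    2000 cells are used for fitting, 500 held out.
    """
    truth = synthetic_model(n_genes=200, seed=7)
    libs = lognormal_library_sizes(2500, seed=5)
    data, v_true, z_true = truth.generate(2500, libs, seed=11)
    train = data.subset_cells(np.arange(2000))
    held = data.subset_cells(np.arange(2000, 2500))
    model = fit(train, ModelConfig(seed=3, max_epochs=100, f_var_warmup_epochs=50))
    return {
        "truth": truth,
        "data": data,
        "train": train,
        "held": held,
        "v_true": v_true,
        "z_true": z_true,
        "mu_true": truth.expression_probs(z_true),
        "model": model,
    }


@pytest.fixture(scope="session")
def fork_run():
    """A forked-trajectory simulation with a trained model, clustering,
    cluster graph and one interpolated path per branch."""
    sim = simulate_states(2000, transition_density=1.0, noise_sigma=0.1, seed=21)
    expr = map_to_expression(sim.noisy_states, d=250, seed=22)
    counts = expression_to_counts(expr, median_depth=4000, seed=23)
    data = simulated_count_matrix(sim, counts)
    model = fit(data, ModelConfig(seed=8, max_epochs=60, f_var_warmup_epochs=30))
    emb = model.encode(data)
    labels = cluster_latent(emb.z, seed=9)
    graph = build_cluster_graph(emb, labels)
    xn = median_normalize_log1p(data.counts)
    cors = np.array(
        [np.corrcoef(xn[:, j], sim.pseudotime)[0, 1] for j in range(data.n_genes)]
    )
    return {
        "sim": sim,
        "data": data,
        "model": model,
        "embedding": emb,
        "labels": labels,
        "graph": graph,
        "pt_correlations": cors,
    }


@pytest.fixture()
def tiny_model():
    """A 5-gene model small enough for importance-sampling oracles,
    with the standard (beta = 1) ELBO."""
    model = synthetic_model(n_genes=5, dim_z=2, dim_v=1, seed=2)
    model.config.beta = 1.0
    return model
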
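# scderail

Joint embedding, trajectory comparison and gene-pattern disruption
scoring for single-cell RNA-seq counts.

When a disease or perturbation *derails* a developmental process, the
question is rarely "which genes differ on average?" but "where along
the process does the deviation start, and which gene programs change
shape or scale?". `scderail` addresses this with three coupled pieces:

1. **A hierarchical negative-binomial VAE.** Each cell gets two
   representations at once: a 2D top-level embedding $v$ (the
   visualization *is* part of the probabilistic model, not a separate
   projection) and latent factors $z \sim \mathcal N(f(v))$ generated
   conditionally on $v$, hence free to be correlated. Raw counts are
   modeled as $x_{ig} \sim \mathrm{NB}(\mu_{ig}\ell_i, \theta_g)$ with
   $\mu_i = \operatorname{softmax}(h(z_i))$, $h$ a single linear layer.
   Training is amortized stochastic variational inference with a
   $\beta$-weighted prior term on $v$.
2. **Trajectories with a shared pseudotime.** Leiden clusters on $z$, a
   minimum spanning tree over cluster centroids in $v$, marker-gene
   endpoints, linear interpolation: arc length along the resulting path
   is the pseudotime. Because conditions are co-embedded, their paths
   share this axis with no alignment or warping, and the decoders
   reconstruct any gene's expected expression along any path, with
   uncertainty bands.
3. **Basis decomposition and disruption scores.** Each gene pattern is
   approximated as $s_{g,c} \sum_k \beta_{g,c,k}\, b_k(t)$: a scale
   times a convex (Dirichlet-weighted) combination of $K$ shared,
   max-normalized temporal bases learned as neural networks under a
   near-GP prior. Comparing a gene between conditions reduces to
   scale disruption $|\Delta \log s|$, shape disruption
   $\lVert\Delta\beta\rVert$, and combined disruption
   $\lVert\Delta\log(s\beta)\rVert$.

A ground-truth simulator (forked 2D trajectories with tunable
transition-region density, pushed through a fixed random nonlinear map
to ~500-dimensional expression) and benchmark metrics (global-structure
preservation by mean Kendall tau over cluster distance profiles,
ordering and divergence scores, smoothed mutation proportions) make the
whole pipeline testable without any external data.

Everything runs on CPU; the variational models train on a small,
finite-difference-validated autodiff engine included in the package.

## Worked example

```sh
python examples/01_embed_simulated_fork.py
```

```
simulated 2292 cells x 500 genes (transition density 0.3, noise 0.1)
global preservation, learned 2D space: 0.896
global preservation, raw PCA-2:        0.681
```

The simulator drew cells along a forked trajectory, kept only 30% of
the cells in the transition window around the branch point, and mapped
them to counts. The learned 2D space preserves the ordering of
cross-cluster distances much better (0.896, max 1) than a raw linear
projection of the same counts (0.681).

```sh
python examples/02_trajectories_and_patterns.py
```

```
12 clusters, MST with 11 edges
start marker g93 (r=-0.92), end marker g65 (r=0.91)
branch 0: cluster path [4, 1, 5, 3, 0, 9, 10, 7, 11], length 5.35
branch 1: cluster path [4, 1, 5, 3, 0, 2, 6, 8], length 4.78
correlation of assigned path time with true pseudotime: 0.99
pattern of g65 along branch 0: 33.8 -> 85.1 counts/5k, peaks at time [5.35]
the interquartile band half-width at the path end is 3.38
```

The two branch trajectories share their first five clusters (the
trunk), then fork; per-cell pseudotime assigned by projection onto the
paths correlates 0.99 with the simulator's truth, and the decoded
pattern of the end marker rises along the path, peaking at its end.

`examples/03_basis_disruption.py` fits the basis decomposition on a
pattern set with five planted perturbed genes and prints the combined
disruption ranking (the top five are exactly the planted genes);
`examples/04_benchmark_metrics.py` demonstrates the ordering,
divergence and mutation-proportion metrics on hand-made layouts.

A thin CLI wraps the same calls
(`scderail {config,train,embed,rotate,trajectory,patterns,basis,disrupt,simulate,benchmark,run}`);
`scderail run --counts ... --out DIR` executes the full pipeline with
stage-level resume. See `docs/methods.md` for the models, defaults and
design decisions.

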
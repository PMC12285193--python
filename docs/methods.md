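# Methods

`scderail` couples three pieces: a hierarchical count model that embeds
cells into a 2D space and a correlated latent space at once, trajectory
machinery that gives different conditions a common pseudotime axis, and
a functional basis decomposition that turns "how did this gene's
program change?" into a comparison of a few interpretable numbers.
This note records the models, their assumptions, the defaults, and the
choices made where more than one design was defensible.

## The hierarchical count model

For cell $i$ with observed library size $\ell_i$ and gene $g$:

$$
v_i \sim \mathcal N(0, I_2), \qquad
z_i \mid v_i \sim \mathcal N\!\big(f_{\text{mean}}(v_i),\, f_{\text{var}}(v_i)\big), \qquad
x_{ig} \mid z_i \sim \mathrm{NB}\!\big(\mu_{ig}\,\ell_i,\ \theta_g\big),
$$

with $\mu_i = \operatorname{softmax}(h(z_i))$. The negative binomial is
in the mean/dispersion convention, $\operatorname{Var} = \mu + \mu^2/\theta$,
so $\theta \to \infty$ recovers Poisson counts. The model always
consumes **raw counts**; library size is the observed row sum.

Architecture: $f$ is one hidden layer of 64 units (ReLU + batch
normalization) whose final affine output is split into mean and
variance halves; $h$ is a single linear layer with a softmax, keeping
the latent-to-expression map close to a loadings matrix; the encoder
$q(z\mid x)$ has one hidden layer of 128, the encoder $q(v\mid z,x)$
one hidden layer of 128 on the concatenation. Encoders receive
$\log(1+x)$ — the generative side is untouched by this; it only
conditions the amortized posterior on a numerically tamer statistic.

Inference is amortized SVI on the ELBO

$$
\textstyle\sum_i \mathbb E_q\Big[\sum_g \log p(x_{ig}\mid z_i)
 + \log\frac{p(z_i\mid v_i)}{q(z_i\mid x_i)}
 + \beta \log\frac{p(v_i)}{q(v_i\mid z_i, x_i)}\Big],
$$

with reparameterized samples drawn $z$ first, then $v$, minibatches of
64, and Adam. $\beta$ (default 0.1) down-weights the prior on $v$,
leaving the 2D plane mostly data-driven; $\beta = 1$ is the standard
ELBO and is what the bound-vs-evidence test uses.

Numerical choices that matter:

* **Positivity.** All variance heads go through a softplus plus a
  $10^{-4}$ floor; dispersions are stored as $\log\theta_g$.
* **Sharp initialization and variance warm-up.** Variance heads start
  at $\operatorname{softplus}^{-1}(0.05)$, and for the first half of
  training (default `f_var_warmup_epochs = 50` of `max_epochs = 100`)
  the variance of $p(z\mid v)$ is held at 0.05. Without this the joint
  optimization reliably stalls in a mutual high-variance plateau: a
  sloppy $f$ gives $q(v\mid z,x)$ weak gradients, an unorganized $v$
  gives $f$ nothing to fit, and both variances sit near their
  softplus-at-zero value (~0.7) indefinitely.
* **Decoder refinement.** After SVI, decoder $f$ is tightened by a
  short Gaussian-likelihood regression of posterior-mean $z$ on
  posterior-mean $v$ (default 1000 Adam steps; encoders untouched).
  SVI trains $f$ against *sampled* $(v, z)$ pairs, while decoding a
  trajectory evaluates $f$ at posterior *means*; the refinement closes
  that gap, and re-estimates $f$'s variance head from the residuals so
  uncertainty bands stay calibrated.
* **Optimizer.** Adam at $5\times10^{-3}$ (not fixed by the model;
  exposed in the config). Early stopping, when enabled, holds out 10%
  of cells and stops after 5 epochs without validation-ELBO
  improvement.
* **Determinism.** Every stochastic routine takes a seed; `fit`,
  `encode` and `decode_with_uncertainty` are bit-reproducible. The
  diagnostic `elbo()` seeds its per-cell noise from the cell id, which
  makes the estimate invariant to cell order and additive over
  disjoint batches.

The ELBO estimator evaluates $\log q$ at the reparameterized samples
with full gradient flow (no analytic-KL simplification), matching the
standard single-sample SVI estimator.

**Rotation.** The likelihood is invariant to orthogonal maps of $v$, so
a post-hoc alignment searches 100 rotation angles × 4 axis flips for
the orthogonal transform maximizing the Pearson correlation between
integer-encoded labels (user-supplied order, ties allowed) and their
target axes. Being orthogonal, it never changes distances, hence never
changes trajectories or any downstream quantity.

**Known limitation.** The amortized family bounds per-cell fidelity:
with the one-hidden-layer $q(v\mid z,x)$ encoder, the posterior-mean
$\hat v$ carries irreducible noise of roughly 0.2 per axis (its
supervised regression floor on the same data), so decode-at-$\hat v$
reconstructions are faithful at the population level (pooled log-scale
correlation with the generating means ≈ 0.95 in the recovery study)
but individual low-depth cells reconstruct less precisely. Trajectory
decoding is unaffected — it evaluates the decoders along smooth paths,
not at single noisy cells.

## Trajectories and shared pseudotime

Cells are Leiden-clustered on $z$ (default 15 neighbors, resolution
0.7) — the latent factors carry finer-grained structure — while the
minimum spanning tree over cluster centroids uses Euclidean distances
in $v$, where the global geometry lives. Trajectory endpoints come from
marker genes: per cluster, the mean of median-library-normalized,
log1p expression over the marker set; the start (end) cluster is the
argmax. The path is the unique MST path between them; an explicit
cluster sequence can be given instead. The polyline through the
ordered centroids, sampled every 0.05 $v$-units of arc length (vertices
always kept), is the trajectory; cumulative arc length is the
pseudotime. Because all conditions live in one embedding, per-condition
paths share this axis with no warping; each cell receives the time of
the nearest polyline point of its own condition's path (ties toward the
smaller time), plus its distance to the path.

Gene patterns along a path decode each path point: $z = f_{\text{mean}}(v)$,
$\mu = \operatorname{softmax}(h(z))$, scaled by a reference library
size; uncertainty bands are the elementwise 25th/50th/75th percentiles
of $\mu$ over 100 draws $z \sim \mathcal N(f_{\text{mean}}(v), f_{\text{var}}(v))$.

Peak calling on a pattern: Gaussian-smooth (σ = 3 grid steps, detection
only), take local maxima where the first difference flips sign, keep
those at or above the midrange (mean of min and max); add the start if
expression begins above midrange with a falling first step or the
global maximum is there; add the end if the global maximum is there. A
constant series has no peaks.

## Basis decomposition and disruption scores

Each gene pattern (gene $g$, condition $c$, on a shared uniform time
grid, default 100 points, linear resampling) is modeled as

$$
\mu_{g,c}(t) \sim \mathcal N\!\Big(s_{g,c}\,\textstyle\sum_{k=1}^K \beta_{g,c,k}\, b_k(t),\ \sigma^2\Big)
\quad\text{independently per grid point (white-noise kernel)},
$$

with $\beta_{g,c} \sim \mathrm{Dir}(\eta, \dots, \eta)$ and each basis
$b_k$ a 1→32→32→1 tanh network whose weights have centered-normal
priors of variance 1/fan-in — a finite-width stand-in for a
Gaussian-process prior in function space. Network outputs are squashed
by a logistic function and divided by their maximum, so bases live in
$(0, 1]$ with maximum exactly 1 and $s_{g,c}$ is the interpretable
amplitude. Defaults $K = 5$, $\eta = 0.25$ ($\eta < 1$ favors sparse,
dominant patterns); both are always reported with results.

Inference: the simplex weights get a logistic-normal variational
family — $u \in \mathbb R^{K-1}$, $q(u) = \mathcal N(\alpha, \operatorname{diag}\sigma_u^2)$,
$\beta = \operatorname{softmax}([u, 0])$ — with the Dirichlet prior
pulled back through the transform *including its log-Jacobian*
($\sum_k \log\beta_k$), i.e. a proper prior term $\eta \sum_k \log\beta_k$.
This matters: a point-mass (MAP) treatment of $\beta$ is improper for
$\eta < 1$ and collapses weights onto the simplex boundary, which
poisons the log-scale combined disruption score with boundary noise.
Basis-network weights are point-estimated under their Gaussian prior;
$\log s$ and a single global $\log\sigma^2$ are point parameters.
Reported weights are Monte-Carlo posterior means (512 draws), which sum
to 1 to float precision. $\sigma^2$ is shared globally; bases are
shared across genes *and* conditions, so a gene's change between
conditions is carried entirely by $(s, \beta)$.

For a condition pair $(c_1, c_2)$, per gene:

* scale disruption $= |\log s_{g,c_1} - \log s_{g,c_2}|$,
* shape disruption $= \lVert \beta_{g,c_1} - \beta_{g,c_2} \rVert_2 \in [0, \sqrt 2]$,
* combined disruption $= \lVert \log(s_{g,c_1}(\beta_{g,c_1}+\varepsilon)) - \log(s_{g,c_2}(\beta_{g,c_2}+\varepsilon)) \rVert_2$,

with $\varepsilon = 10^{-6}$ guarding the log at zero weights. The norm
is Euclidean. All three are symmetric and vanish when the
decompositions coincide.

## The simulator and the metrics

**Fork.** A piecewise-linear trunk from $(0,0)$ to $(4,0)$ splitting
into arms ending at $(8,\pm 2)$; positions are sampled uniformly in arc
length along each branch path (branch chosen 50/50, so the shared trunk
is sampled at twice the arm density). A transition window — arc length
$[3.5, 4.5]$ along each branch, i.e. around the branch point — retains
points with probability equal to the *transition density* (0 = rare
transitions fully removed, 1 = keep everything). Survivors get
isotropic Gaussian noise (default σ = 0.1); the first coordinate of the
un-noised state is the ground-truth pseudotime. All geometry is
configurable and recorded in the dataset's spec.

**Expression.** A fixed random feed-forward map (2 → 64 → 64 → d,
ReLU, weights drawn once per seed, d = 500 by default) sends noisy
states to real-valued expression. The count model consumes counts, so a
bridge converts expression to counts: softplus to a positive rate,
per-cell scaling to a log-normal sequencing depth (median 5000,
matching typical droplet data), Poisson sampling. The simulator
emulates continuous forked geometry, rare transition states and count
noise; it does **not** emulate batch effects, doublets, ambient RNA or
gene-specific dropout, so passing tests here speaks to geometry
recovery, not to robustness against those artifacts.

**Global preservation.** k-means (20 clusters, 10 restarts, seeded) on
the ground-truth states; for each ordered cluster pair the *sum* of all
cross-cluster pairwise Euclidean distances in each space; the score is
the mean over clusters of the Kendall tau-b correlation between the two
cross-cluster distance profiles (self-distances, identically zero in
both spaces, are excluded from the profile). The score is exactly 1 for
any isometry-plus-scaling of the truth and is invariant to monotone
distance transforms.

**Ordering / divergence.** Between-state distance is the mean pairwise
cell distance (robust to unequal group sizes). The ordering score is
the ratio of summed non-consecutive to consecutive distances along a
stated order — maximal when states are laid out in that order. The
divergence score sums distances between all non-anchor state pairs
across two conditions and subtracts twice the anchor-pair distance —
positive geometry: shared origin, diverging termini.

**Mutation proportion.** Per cell, $m/(m + w + 10^{-10})$ where $m$ and
$w$ count mutant and wild-type calls among the 30 nearest neighbors in
a 100-component truncated-SVD space of median-normalized log1p counts.

## Study sizes used by the test suite

Chosen so each study is informative at desk scale: parameter recovery
fits 2000 cells × 200 genes (500 held out) generated by a known model
with dispersion 20 and log-normal depths around 5000; the fork
benchmark uses 2500 sampled positions, d = 500, five seeds, against a
raw 2-component PCA baseline and a flat (no-top-space) NB VAE
visualized with UMAP; basis recovery uses 20 genes × 2 conditions ×
100 grid points at noise σ = 0.01.

## Implementation note

Both variational models are trained on a small reverse-mode automatic
differentiation engine written for this package (`scderail.autodiff`):
a numpy `Tensor` with a backward tape, dense/batch-norm layers, the
negative-binomial log-pmf as a differentiable primitive, and Adam. Its
gradients are validated against central finite differences on the exact
graphs the models use. It supports CPU only, which is sufficient at the
scales above (full test suite in minutes on one core).
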
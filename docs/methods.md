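# Methods

## Measures

All indices in this package report a **numbers equivalent**: the number
of states (or, on continuous spaces, the volume of the domain) of an
idealized uniform system with the same heterogeneity.

**Categorical Rényi heterogeneity.** `Πq(p) = (Σ pᵢ^q)^(1/(1−q))` with
the conventions: `0^0 = 0` inside the `q=0` sum (so `Π₀` is observed
richness); `|q−1| < 1e-10` is evaluated as the perplexity limit
`exp(−Σ pᵢ log pᵢ)`; `q=∞` is requested only by an explicit infinity
sentinel and returns `1/max pᵢ`.  Power sums are accumulated in log space
(log-sum-exp over `q·log pᵢ`, skipping zero entries), which keeps orders
up to several hundred stable.

**Decomposition.** For a row-stochastic matrix `P` with subsystem weights
`w`, pooled heterogeneity is `Πq` of the mixture `Σ wᵢ pᵢ`; within-group
heterogeneity is Jost's weighted power mean
`[Σᵢ wᵢ^q (Σⱼ pᵢⱼ^q) / Σₖ wₖ^q]^(1/(1−q))`, with the `q=1` limit
`exp(Σ wᵢ H(pᵢ))` and — a case the original formulation leaves open — the
`q=∞` limit taken directly from the formula,
`max_k wₖ / max_{i,j}(wᵢ pᵢⱼ)`.  Zero-weight subsystems are excluded
(this is the `0^0 = 0` convention applied to weights, and makes the `q=0`
within-term the average richness of the supported subsystems).  Between =
pooled / within holds identically by construction; with unequal weights
and `q ∉ {0, 1}` the within term is not guaranteed to lower-bound the
pooled term, and the library logs a warning rather than refusing.

**Functional comparators.** `Q̂e = (1 − Q₁(D̃,p))⁻¹` with `D̃` affinely
rescaled onto [0,1] by default (opt-out flag for distances already on a
[0,1] scale); `Fq = [Qq/Q₁]^(1/(2(1−q)))` where
`Qq = Σ Dᵢⱼ (pᵢpⱼ)^q`; `Lq = [Σ pᵢ((Sp)ᵢ)^(q−1)]^(1/(1−q))` with
similarity `S = e^(−uD)`.  The `Fq` order-1 limit is evaluated in closed
form, `F₁ = exp(−Σ Dᵢⱼ pᵢpⱼ log(pᵢpⱼ) / (2Q₁))`, obtained by
differentiating `log Qq` at `q=1`; this is exact and better conditioned
than two-sided bracketing at `q = 1 ± ε`, which the unit tests retain
only as a cross-check.  Metric and ultrametric checks enumerate all
triples with an absolute tolerance of 1e-9, so the equilateral boundary
case `h = b√3/2` classifies as ultrametric.

The 3-state triangle family uses `p(κ) ∝ (1, √κ, κ)`, the unique smooth
one-parameter interpolant through the degenerate (κ=0), even (κ=1) and
opposite-degenerate (κ→∞) anchors, and the isosceles distance matrix with
base `b` and apex height `h`.

## Representational heterogeneity

Categorical latents reuse the decomposition machinery verbatim on the
posterior matrix.  Continuous latents replace sums by integrals:
`Πq = (∫ f^q dz)^(1/(1−q))` is the effective support volume and can be
below 1 (a posterior more concentrated than a unit box).  `q=0` is
undefined for densities with unbounded support and raises.

**Gaussian closed forms.**  For `N(μ, Σ)` on an `nz`-dimensional space:

```
Πq(Σ) = (2π)^(nz/2) |Σ|^(1/2) · c(q),
c(1) = e^(nz/2),   c(∞) = 1,   c(q) = q^(nz/(2(q−1))) otherwise.
```

The within-observation term is derived by substituting the Gaussian power
integral `∫ N^q = (2π)^(nz(1−q)/2) q^(−nz/2) |Σ|^((1−q)/2)` into the
integral form of the within formula; its `q→∞` limit is
`max_k wₖ · min_i [(2π)^(nz/2)|Σᵢ|^(1/2) / wᵢ]`.  Because closed-form
transcription errors are easy to make here, the test suite treats blind
adaptive quadrature of the defining integrals as ground truth and checks
both closed forms against it (rel. tol. 1e-6 at moderate orders, 1e-3 at
the order-1000 approximation of `q=∞`) over random well-conditioned
covariances in one and two dimensions.

**Pooling.**  Parametric pooling moment-matches a single Gaussian
(`μ* = Σ wᵢμᵢ`, law of total covariance for `Σ*`); non-parametric pooling
integrates the mixture density itself — adaptive quadrature on a box of
±8 pooled standard deviations per axis up to three latent dimensions,
otherwise self-normalized Monte Carlo (the mixture is its own importance
distribution, estimating `E_f[f^(q−1)]`) with a reported relative
standard error and a warning above 2%.  The default Monte-Carlo seed is
20200417 and every sampler accepts an explicit seed.  No ordering between
the two pooling results is asserted anywhere: parametric pooling assumes
mass between clusters and typically inflates the pooled volume for
separated components.  Subset analyses take a row subset with
renormalized weights and decompose the subset as its own ensemble.

Covariances are accepted as full matrices or diagonal (log-)variance rows
(the VAE encoder convention); a square symmetric 2-D array is read as a
single full covariance, anything else with `nz` columns as variance rows.
PSD repair symmetrizes and clips eigenvalues only when the most negative
eigenvalue is above −1e-9; anything worse is rejected as data corruption
rather than round-off.

## Beta-mixture benchmark

The benchmark system is fully analytic.  The Bayes threshold solves
`p(z=1|x) = p(z=2|x)`; since the posterior log-odds is affine in
`logit(x)`, the root is obtained exactly by inverting that map rather
than transcribing a closed-form expression; the degenerate branches
(θ₂=θ₃, or θ₁ ∈ {0,1}) place the threshold at 0 or 1.  Pooled
classification frequencies use `scipy.special.betainc` over `[τ, 1]`.
Because the classifier's posteriors are degenerate, within-heterogeneity
is identically 1 and between equals pooled — the effective number of
mixture components.

`E|X−Y|` between independent beta variables is computed by the exact
one-dimensional reduction `∫₀¹ [F_X + F_Y − 2F_X F_Y] dt` (the
probability that `t` separates the pair, integrated over `t`), quadrature
tolerance 1e-12; the two-dimensional double integral serves as the
independent oracle in tests.  Comparator distance matrices default to a
zero diagonal (the distance-matrix convention); the
`self_distance="expected"` variant uses the expected within-component
distance `E|X−X′|` on the diagonal, evaluated outside the strict
zero-diagonal types.  The exact weight-invariance of `Lq` at θ₂=θ₃ holds
only under the expected-self-distance convention (identical components
make every expected pairwise distance equal, hence `S` constant); the
qualitative failure — `Lq > 1` for an effectively unimodal system — holds
under both.  `u` for the similarity transform defaults to 1 and is
exposed everywhere.

## Synthetic generators

Generators are pure functions of their arguments (seed included):
symmetric-Dirichlet probability vectors; disjoint block-replicated
ensembles (each subsystem the same distribution on its own column block,
equal weights — the exact hypotheses of the replication principle);
Gaussian cluster sets with means on a seeded random sphere of radius
`separation` and random well-conditioned covariances scaled by
`covariance_scale`; and ancestral beta-mixture samples.  These emulate
the *structure* of encoder outputs (per-observation mean and covariance),
not any particular trained model: passing tests show the measures behave
correctly on well-specified posteriors, and say nothing about the
adequacy of any representational model for real data — model validation
is a domain problem outside this package's scope.

## Problem sizes and numerical choices

Quadrature oracles run on 1-D and 2-D latent spaces with 10 random
covariances per dimension and orders {0.5, 1, 2, 5, 1000}; replication is
tested for N ∈ {2, 3, 5} over q ∈ {0, 0.5, 1, 2, ∞}; the transfer
principle on 100 Dirichlet draws; Monte-Carlo agreement of the
classification frequencies at 10⁵ draws within three standard errors.
Cluster-separation demonstrations use separations of ~10 latent units
against covariances of order 0.3, large enough that inter-cluster overlap
is below 1e-7 while keeping the integration boxes modest.

Known limitations: no finite-sample estimation theory (probabilities are
treated as known — no bias correction or rarefaction); only Gaussian
parametric families ship for continuous latents (the density interface
accepts arbitrary callables up to 3-D); quadrature beyond three latent
dimensions is delegated to Monte Carlo; and between-heterogeneity below 1
in the continuous case is flagged with a warning, not prevented — the
conditions under which it can occur are not characterized here.
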
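# Methods

## The haplotype-network model

`hapnet` models the effects of distinct haplotypes as a Gaussian Markov
random field on a known phylogeny encoded as a DAG (child → parent edges,
one mutation per edge). The construction is a stationary AR(1) process
carried along the graph:

* a *starting* haplotype (no parents) has the stationary law
  `h ~ N(0, σ²_hm)`; several starting haplotypes are allowed and are
  independent;
* a haplotype with parents `h_1..h_k` follows
  `h_i | parents ~ N((ρ/k) Σ_j h_j, σ²_hc/k)` with
  `σ²_hc = σ²_hm (1 − ρ²)` and `|ρ| < 1` — the multi-parent case averages k
  conditionally independent AR(1) contributions, one per parent.

Writing `h = T(ρ) ε` with independent innovations
`ε ~ N(0, D(ρ) σ²_hc)`, the joint precision
`Q = (1/σ²_hc) T⁻ᵀ D⁻¹ T⁻¹` is assembled in one pass over haplotypes
(triplet form, symmetric by construction, never densified during
assembly): `1 − ρ²` on a starting node's diagonal; `k_i` on a non-starting
diagonal; `−ρ` between child and each parent; `ρ²/k_i` on each parent's
diagonal and between every pair of parents sharing that child. Internally Q
is held as a polynomial `Q0 + ρ Q1 + ρ² Q2` in sparse form so it can be
re-assembled for many ρ values at negligible cost. The log-determinant is
exact and factorisation-free: `det T⁻¹ = 1`, so
`log det Q = Σ log D⁻¹_ii − n log σ²_hc`, with one `(1 − ρ²)` factor per
starting haplotype (s roots give exponent s/2 in the density — the
single-root formula is a special case).

Assumptions and known departures from them:

* **Stationarity holds on trees only.** With k independent parents a
  child's marginal variance is smaller than σ²_hm (e.g. σ²_hm/3 plus the
  ρ² terms for three independent roots). The construction is implemented
  exactly as defined and the non-stationarity documented rather than
  renormalised away; consequently "ρ = 0 ⇒ Q = I/σ²_hm" also holds only for
  single-parent DAGs (multi-parent nodes keep conditional variance
  σ²_hc/k).
* **One mutation per edge.** Multi-mutation edges are split by inserting
  phantom haplotypes `child.p1, child.p2, …` (parent → child order). Only
  the path length matters to the model, so the arbitrary assignment of
  mutations to phantoms is inconsequential. Phantoms carry no phenotypes
  and no allele row; they are excluded from scoring by default.
* **The phylogeny is given.** Inferring it is out of scope; Newick trees
  (`dag_from_tree`, integer branch "lengths" = mutation counts) and TSV
  edge lists are accepted. A block-diagonal multi-region variant
  (`build_multiregion_precision`, shared ρ and σ²_hc across regions) is
  provided for pre-partitioned segments; recombination itself is not
  modelled.

A dense covariance oracle `V = T D Tᵀ σ²_hc` (explicit inversion of the
unit-triangular `T⁻¹`) exists purely for testing and small-n work.

## Phenotype model and inference

`y = Xβ + f_1 + … + f_s + Z h + e` with Gaussian likelihood on centred and
scaled phenotypes. `β ~ N(0, 1000·I)` (configurable); extra random terms are
i.i.d. or carry a user-supplied covariance/precision (e.g. a pedigree
relationship matrix); the haplotype term is one of HN (`Q` above), IH
(`I/σ²_I`), or mutation (`h = U v`, `v ~ N(0, I σ²_v)` with the 0/1 allele
matrix `U`). There is **no global intercept**: an intercept and the
haplotype level are unidentifiable as ρ → 1, so the level is absorbed by
`h`; constant columns in `X` are rejected (override `allow_intercept`), and
a soft sum-to-zero constraint on `h` is available but off by default.

Inference exploits that the likelihood is Gaussian, so for fixed
hyper-parameters θ the latent posterior is exactly Gaussian: one Cholesky
factorisation of `P(θ) + WᵀW/σ²_e` (prior precision plus scaled normal
equations) yields the conditional mean, covariance and the marginal
likelihood, with log-determinants read off the factor diagonal. The
hyper-parameters — internally `log` variances and
`log((1+ρ)/(1−ρ))` — are integrated on a grid: quasi-Newton-free
Nelder-Mead mode search, finite-difference Hessian, Cartesian grid at
mode ± 3 sd with 7 points per dimension, pruned where the log-posterior
drops more than 10 below the mode, weights normalised. All reported latent
marginals are the mixture moments over the grid (the mixtures are close to
Gaussian, and scoring treats them as such). This is the structure of
latent-Gaussian-model machinery, exact here because no Laplace
approximation is needed; ≤ 5 hyper-parameters arise in any configuration
shipped, so a full grid is tractable and deterministic. A failed mode
search flags `converged=False` on the results instead of raising; study
aggregation drops such replicates.

Hyper-parameter marginal quantiles interpolate the grid log-density
piecewise-linearly (piecewise-exponential density) with slope-matched
exponential tails beyond the outer nodes. This matters: treating grid cells
as uniform blocks clips the skewed upper tail of the ρ marginal and costs
several points of frequentist coverage; with the interpolation, default-grid
95% intervals match 21-point-grid intervals to ~0.002 and cover the true ρ
in ≈96% of replicates at the study scale.

Derived quantities: mutation effects from a haplotype fit via the left
inverse `v = (UᵀU)⁻¹ Uᵀ h` applied to the posterior of `h` (variances from
`M Cov(h) Mᵀ` with the full grid-mixture covariance restricted to
non-phantom haplotypes; a rank check names collinear site sets);
`σ²_hc = σ²_hm (1 − ρ²)` summarised by drawing 10,000 joint (ρ, σ²_hm)
samples from the weighted grid (cell by weight, uniform within cell),
seeded.

## Priors

Penalised-complexity (PC) priors throughout. Standard deviations get
`σ ~ Exp(λ)`, `λ = −ln(α)/u`, i.e. `P(σ > u) = α`; defaults u = 0.1,
α = 0.8 for every sd (residual, haplotype-marginal, mutation, extra
terms) — weakly informative on phenotypes scaled to unit-ish variance. The
AR(1) autocorrelation gets the PC prior with **base model ρ = 1** (most
mutations are neutral, so neighbouring haplotypes are expected to have
nearly identical effects): exponential density on the complexity distance
`d(ρ) = √(1 − ρ)`, truncated to `d ∈ (0, √2)`, rate calibrated numerically
so `P(ρ > u_ρ) = α_ρ`; defaults u_ρ = 0.7, α_ρ = 0.8. Admissibility
requires `(1 − u_ρ)/2 < α_ρ < 1`, and the truncated family can only reach
tail probabilities above `√((1−u_ρ)/2)` (its rate → 0 limit); values between
the two bounds raise a calibration error. Any monotone rescaling of d only
rescales the rate — the (u, α) tail statement is the interface that is
tested. Fixed effects keep the Gaussian N(0, 1000) prior, not a PC prior.

## Synthetic data

The generator emulates a no-recombination, haploid study design:

* **Phylogeny**: sequential random attachment under infinite sites — each
  new haplotype copies a uniformly chosen existing one and adds one newly
  mutated site, giving n haplotypes, n − 1 sites, every edge one mutation,
  single root, U of full column rank. Study dimensions: n = 107 haplotypes,
  106 sites, p = 400 individuals.
* **HN simulator**: ancestral recursion of the AR(1) law with σ²_hc = 1 by
  convention, so the residual-variance ratios σ²_e/σ²_hc ∈ {0.5, 1, 2} are
  σ²_e directly; ρ ∈ {0.1, 0.3, 0.5, 0.7, 0.9}.
* **Mutation simulator**: spike-and-slab per-site effects (causal with
  probability λ ∈ {0.1, …, 0.9}, Gaussian when causal; the causal mask is
  redrawn up to 100 times if empty), then v rescaled so the sample variance
  (ddof = 1) of h = U v is exactly 1; σ²_e ∈ {0.5, 1, 2}.
* **Observation designs**: `all_observed` — exactly round(0.15 n)
  haplotypes carried by exactly one individual, every other haplotype by at
  least two (double round-robin then uniform fill; this makes the
  once/several strata exact and needs p ≥ 2n − round(0.15 n));
  `some_unobserved` — exactly round(0.15 n) haplotypes with no carrier, the
  rest covered round-robin then filled uniformly.

All randomness flows from one seed through numpy `SeedSequence` substreams
(phylogeny, effects, incidence, residuals are separate streams), so
datasets are bit-identical across runs and stage-level reproducibility
survives pipeline reordering.

What the generator does **not** emulate: coalescent-shaped haplotype
frequency spectra (the incidence design is imposed, not sampled),
recombination, diploidy, selection, genotyping error, and real linkage
structure. Passing the replication tests therefore demonstrates the
estimator's behaviour under the stated generative models, not performance
on real data. (An msprime-based coalescent mutation tree was evaluated as an
alternative topology source during development; model-comparison aggregates
were statistically indistinguishable from the attachment generator's, so the
simpler generator is the single engine.)

## Replication studies and scoring

Fits are scored against simulated truth with the closed-form Gaussian CRPS
of each marginal's mixture mean and sd (`σ = 0` degrades to absolute
error); an exact Gaussian-mixture CRPS is available behind a flag for
sensitivity checks. Pairs of models are compared by RCRPS,
`log(Σ CRPS_A / Σ CRPS_B)` over the same haplotype set — computed per
replicate and averaged across replicates (the per-pooled-sum alternative is
a one-line change). Haplotypes are stratified by phenotype-observation
count (never / once / several; phantoms always "never"). `replicate_study`
runs cells × scenarios × replicates on one shared phylogeny per study,
fits the requested models, drops replicates with any non-converged fit
(cells with > 50% drops are flagged, the run continues) and emits a tidy
long-format table. Variance-explained proportions divide each posterior
variance component by their sum, using σ²_hm (not σ²_hc) for the HN term.

Problem sizes used in the shipped studies were chosen to keep a full run on
one CPU in minutes: the parameter-recovery check uses 50 replicates at the
full 107 × 400 scale; the 15-cell HN-simulation pattern study uses 20
replicates per cell; the four-cell mutation-effect comparison
(`scripts/acceptance.py`) uses 50 replicates per cell.

On reproducing the published magnitudes of the mutation-effect comparison:
with a regenerated phylogeny the qualitative structure is stable (the
comparison worsens for the HN model as residual variance grows and as
causal sites become rarer, and is near zero when most sites are causal),
but the absolute log-ratios are tree- and data-dependent; values on a
regenerated tree should be read as sign-and-magnitude-class estimates, not
digit-level replicas.

## Numerical choices and limitations

* Dense Cholesky is used for the joint latent precision (latent dimensions
  here are ≤ a few hundred); the precision assembly itself stays sparse and
  scales to large n. Very large latent fields would need a sparse
  factorisation backend in `_conditional_core`.
* Internal-scale hyper-parameters are clamped to ±40 before
  exponentiation; non-positive-definite evaluations score −∞ during mode
  search rather than aborting.
* The soft sum-to-zero constraint adds `10⁸ · 1 1ᵀ` to the haplotype block
  rather than conditioning exactly.
* Grid integration is deterministic; its accuracy is set by
  `GridSettings` (points per dimension, extent, pruning). Doubling the
  resolution moves latent means by far less than a posterior sd on the test
  fixtures.
* The model is Gaussian throughout; heavy-tailed phenotypes or a point mass
  of identical haplotype effects violate its assumptions. Non-Gaussian
  likelihoods, Ornstein-Uhlenbeck/branch-length kernels,
  mutation-type-specific ρ and probabilistic networks are out of scope.
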
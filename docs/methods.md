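# Methods

## Model and assumptions

Each node's signal is treated as a zero-mean, stationary, ergodic Gaussian
process within a state; a node pair in one state is summarized by its 2×2
covariance. All inference concerns the pair of covariances (Σ_A, Σ_B) of
the two states. Gaussianity enters twice: the Wishart sampling model for
observed covariances, and the Fisher z test for correlation change.
Nothing in the deterministic bounds requires Gaussianity — they are pure
second-moment statements.

An **additive signal change** in a node is `X_B = X_A + X_N` with the
added component non-negatively correlated with the signal it joins
(mirrored when variance decreases: the removed component must correlate
non-negatively with what remains). Both the direction rule and the
added-variance cap `σ²_N ≤ |Δσ²|` reduce to the single linear constraint
`cov(X_A, X_B) ≥ min(σ²_A, σ²_B)`.

## The bound optimizations

Given ρ_A, both states' variances and a class, we need the minimum and
maximum state-B correlation attainable by class members. We work with
explicit vectors in a 4-dimensional inner-product space (signals ↦
vectors, covariances ↦ inner products), which makes joint positive
semi-definiteness automatic and leaves a smooth low-dimensional problem:

* **General additive class.** Free quantities: the two own-state inner
  products g_x = cov(X_A, X_B) ∈ [min(σ²_XA, σ²_XB), σ_XA σ_XB] (same for
  Y) and the orientations of the state-B vectors. For fixed (g_x, g_y) the
  orientation problem reduces to two angles, and maximization over one of
  them is closed-form (a cosine/sine extremum), leaving a 3-parameter
  smooth objective. It is solved by a dense vectorized grid plus
  Nelder–Mead refinement from the best grid points and eight deterministic
  corner starts (tolerance 1e−10 in parameters).
* **Common-signal subclass.** A shared unit latent is characterized by
  its correlations (c_x, c_y) with the two state-A signals, confined to
  the ellipse `c_x² + c_y² − 2ρ_A c_x c_y ≤ 1 − ρ_A²`; the per-node scales
  follow from the variance equations (for a variance decrease only the
  smaller quadratic root respects the cap). The objective has square-root
  cusps along the per-node constraint lines, so extrema are searched per
  boundary family — ellipse interior (2-D), ellipse edge (1-D), each
  constraint line (1-D) — by dense grids with iterative shrinking. This
  class can be genuinely empty (e.g. a strong variance decrease in one
  node with an increase in the other at high |ρ_A|); that is reported as
  an error (scalar API) or NaN (batch API) and treated as outright
  rejection by the class test.
* **Negative initial correlation** is handled by sign-flipping one
  channel, solving, and mapping back; common signals then enter the two
  nodes with opposite signs so that they still push |ρ| upward.

The returned extremal configurations are full second-moment
specifications (scales plus five correlations) that forward-evaluate onto
the interval endpoints to 1e−6 and are used to generate the Monte-Carlo
null data. Ties are broken toward minimal total added variance. Variance
changes below 1e−10 (relative) are snapped to zero so that optimizer noise
cannot produce spuriously non-collapsed intervals.

The test suite cross-checks both solvers against an independent
brute-force search written in a different parameterization (scales + free
cross-correlations, PSD decided through a Schur complement, which also
yields the optimal added-signal correlation in closed form); agreement is
within 1e−3 over 100 random instances.

A consequence of the constraint set worth stating explicitly: with a 20%
SD increase in both nodes at ρ_A = 0.58, the common-signal interval is
[0.708, 0.887] and the general additive class reaches exactly 1.0 — an
addition to each node of (a scaled copy of) the part of the other node it
lacks is feasible under the direction and cap constraints and makes the
two state-B signals identical. Additive changes with this much added
variance are thus compatible with full synchronization; only smaller
variance changes make the "synchronization without variance change"
signature detectable as non-additive.

## Effective degrees of freedom

Autocorrelation inflates the sampling variance of covariance estimates.
Each channel is fitted with an AR(p) model (AIC order selection, p ≤ 10);
the implied autocorrelation function ρ_k gives the variance-inflation
factor `1 + 2Σ_k ρ_k²` for second moments (for AR(1) with coefficient φ
this is `(1+φ²)/(1−φ²)`; note it is *not* the `(1+φ)/(1−φ)` factor that
applies to the sample mean — simulation of the sample-correlation
variance confirms the squared-autocorrelation form). The pair dof is the
harmonic mean of the channels' `n / VIF`. Below 30 time points, or when
an AR fit is non-stationary, the estimator falls back to `n − 1` with a
warning. Dof is estimated per state per pair; whether pooling across
states or pairs would be preferable is a sensitivity question, not
settled here.

## Monte-Carlo class tests

1. Putative true state-A covariances are drawn from
   `InvWishart(df = ν_A, scale = ν_A Q_A)` — a flat prior over
   covariances combined with the Wishart likelihood at the effective dof
   ν_A — and true state-B variances from the matching one-dimensional
   marginals (inverse-gamma). Numerically degenerate draws are rejected
   and redrawn (counted; >99% rejection aborts with a diagnostic).
2. Per draw, the tested class's extremal true state-B correlations are
   computed (for the uncorrelated class, the single closed-form point) and
   an *observed* correlation is sampled at the state-B dof through a
   Bartlett-decomposition Wishart draw.
3. The class is rejected when the observed ρ_B lies below the
   (1−level)/2 quantile of the min-extreme distribution or above the
   mirrored quantile of the max-extreme distribution (default level 0.95,
   type-7 empirical quantiles, tails split equally). Because most class
   members produce smaller changes than the extremal one, this is
   conservative by construction; p-values are reported with add-one
   smoothing `(r+1)/(n+1)`.

Significance of the correlation change itself uses the Fisher z statistic
with standard error `sqrt(1/(ν_A−3) + 1/(ν_B−3))` — calibrated, fast and
independent of the ASC machinery. Across a network, Benjamini–Hochberg
FDR (default α = 0.2) is applied to the change p-values; class tests run
only on surviving edges, each with a child seed derived from the root
seed and the edge index so results are reproducible and order-independent.
Edge categories follow most-specific-first precedence (uncorrelated,
common, other additive, non-additive), so subclass edges are not counted
under the general class and the four categories partition the significant
edges. When both subclasses survive, a secondary annotation records
whether variance and |correlation| moved together (suggesting a common
signal) or oppositely (suggesting uncorrelated signal); the primary label
still follows precedence. The choice of precedence over any data-driven
tie-break is a deliberate simplification: it is deterministic and
reviewable, at the cost of occasionally labelling a genuinely common
change as uncorrelated when both explanations fit.

## Synthetic data

The generator realizes the model directly: Gaussian series with a
prescribed covariance (Cholesky mixing), optional AR(1) autocorrelation
per node (exact spectra when nodes share a coefficient, approximate
otherwise — mixing AR processes with different coefficients changes
marginal spectra), and state-B injections constructed sample-path-wise:
an independent component per node (uncorrelated class), one shared latent
across targets (common class; optionally correlated with existing
activity through the standardized mean of the targets' signals), or an
alternating-sign shared latent as a non-additive negative control.
Injection scales solve the variance equation for a target fractional
variance increase.

Reference scenarios:

* **Two-node**: unit variances, ρ_A = 0.58, 230 time points, additions
  raising both SDs by 20% (variance ×1.44) — variants per class.
* **Ten-node network**: nodes 1–6 pairwise correlated with values drawn
  once (fixed construction seed) from [0.3, 0.7], nodes 7–10 weakly
  coupled, nearest-PD repair; one shared latent, orthogonal to existing
  activity, injected into nodes 1–3 for a +20% variance increase. Which
  pairs carry the initial correlations is a fixture choice, documented
  here, not something the scenario definition pins down.

A spectra-matched surrogate generator refits each channel's lag-1
autocorrelation from a template recording and produces fresh realizations
at a target covariance, for building null data that mimic real recordings'
size, spectra and covariance.

What the generator does *not* emulate: hemodynamic filtering, motion and
physiological artefacts, non-Gaussian amplitude distributions,
non-stationarity within a state, and cross-spectral structure beyond
shared AR(1). Passing tests therefore demonstrate correctness of the
inference machinery under its own assumptions, not robustness to the full
complexity of real recordings.

## Problem sizes and numerical choices

The validation suite runs the ten-node recovery at 2000 time points per
state with 500 Monte-Carlo iterations, calibration checks at 16–24
replicates of 250 iterations, and oracle equivalence on 100 random
instances — sizes chosen so the whole suite completes in a few minutes on
one CPU while keeping binomial error bars informative. The batch bound
solvers used inside the Monte-Carlo loop trade the scalar solvers' 1e−8
refinement for grid-shrink accuracy ~1e−4, far below Monte-Carlo noise.

Recovery-test tolerances deserve a note: a class test calibrated at the
5% level *must* misclassify roughly one edge in twenty, so requiring zero
misses across the ~10 classified edges of the ten-node scenario would
contradict the calibration requirement. The recovery assertions therefore
allow the binomially expected number of single-edge misses (e.g. at least
two of the three injected edges significant and labelled common, at least
75% of decorrelated cross edges labelled uncorrelated) while keeping the
zero-tolerance checks where the procedure should truly never fire (no
non-additive labels anywhere in the scenario).

## Known limitations

* Bivariate only: no partial-correlation variant; shared drive from a
  third recorded node is not partialled out.
* Single-recording inference: no group-level random-effects layer;
  concatenate sessions or analyse them separately.
* The flat-prior inverse-Wishart posterior is one defensible choice; at
  low effective dof (< ~50) the prior's influence is noticeable and the
  class tests become more conservative.
* The common-signal class with large admissible variance changes is wide;
  rejecting it requires either small variance changes or large effects.
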
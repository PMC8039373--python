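# Methods

## Model

`mmjoint` fits a hierarchical joint model for a person-by-item binary response
matrix Y and a positive response-time matrix T. Accuracy follows a
multidimensional Rasch model, `logit P(Y_ni=1) = θ_n·q_i + d_i`, and log times
follow `log T_ni ~ N(ξ_i − τ_n·q_i, ω_i⁻²)`, with one binary Q-matrix row
`q_i` per item marking the single dimension it measures. Y and log T are
conditionally independent given the person and item parameters (the standard
hierarchical-modeling assumption); all dependence between accuracy and speed
flows through the person-level covariance.

Person vectors `(θ_n, τ_n)` are multivariate normal with mean fixed at **0**
— this identifies the latent scales, so the mean is never sampled. Item pairs
`(d_i, ξ_i)` are bivariate normal with free mean `(μ_d, μ_ξ)` and covariance
`Σ_item`; the time precisions ω_i are independent across items.

Three variants share one code path, differing only in the speed loading
matrix: `mmj` (speed Q = ability Q, K speed factors), `msj` (a single all-ones
speed column), and `slrt` (times only, no accuracy block). With K = 1 all
variants coincide exactly.

Natural logarithms are used for times throughout, and times are carried in
seconds. Missing Y and missing T cells are masked independently per cell and
contribute exactly zero to every likelihood and conditional (the file readers
additionally coerce non-positive times to missing, with a logged count). ω is
exposed everywhere as the reciprocal residual SD; the sampler works internally
with the precision ω².

## Priors

Weakly informative hierarchical priors:

* `Σ_person ~ InvWishart(I_P, df = P)` with P the person dimension (2K for
  `mmj`, K+1 for `msj`);
* `(d_i, ξ_i) ~ BVN((μ_d, μ_ξ), Σ_item)`, `Σ_item ~ InvWishart(I_2, 2)`;
* `μ_d ~ Normal(0, 2)`, `μ_ξ ~ Normal(4.3, 2)` — the second argument is read
  as a **variance** by default. The precision reading (BUGS/JAGS convention)
  is available via `PriorSpec(hyperprior_scale_is="precision")`; it shrinks
  the item-level means noticeably at short test lengths (about 13% for μ_d at
  I = 15), which is visible in hyper-mean recovery, while the variance reading
  leaves them essentially unshrunk. Sensitivity between the two readings is
  confined to μ_d/μ_ξ; item, person and covariance recovery are unaffected.
* `ω_i⁻² ~ InvGamma(1, 1)` on the residual variance, i.e. Gamma(1, 1) on the
  precision, updated conjugately.

## Sampler

One sweep per iteration of a Metropolis-within-Gibbs scheme:

1. **θ_n** (all persons in parallel): adaptive random-walk Metropolis on the
   K-vector, using the conditional prior `θ|τ` from `Σ_person`. The isotropic
   proposal scale is tuned by Robbins–Monro during burn-in toward an
   acceptance rate of 0.35 and frozen afterwards (so the post-burn-in chain is
   Markov). Acceptance rates are recorded and sit in (0.1, 0.7).
2. **τ_n**: exact multivariate-normal conditional (the time model is linear
   Gaussian in τ; with a between-item Q the likelihood precision is diagonal).
3. **d_i** (all items in parallel): adaptive random-walk Metropolis with the
   conditional prior `d|ξ` from `Σ_item`.
4. **ξ_i**: exact normal conditional.
5. **Location recentering** (exact Gibbs): for each dimension k the
   likelihood is invariant under `θ_·k += δ, d_{i∈k} −= δ` and under
   `τ_·k += δ, ξ_{i∈k} += δ`; the conditional of δ under the Gaussian priors
   is normal and is sampled exactly. Without this move the item-location
   parameters mix by a slow random walk; with it, full-length runs reach
   max-PSRF ≈ 1.05–1.08.
6. **ω_i²**: conjugate Gamma. 7. **Σ_person**: conjugate inverse-Wishart.
8. **(μ_d, μ_ξ), Σ_item**: conjugate normal / inverse-Wishart.

Chains are initialized from jittered method-of-moments values (logit of the
item proportion-correct, item mean log-times, zero person parameters, identity
covariances, plus chain-specific noise). Prior draws were rejected as starting
points because the inverse-Wishart priors with df = dimension have no finite
mean and can start a chain absurdly far from the typical set; jittered
moment-based starts are dispersed enough for the between-chain PSRF to be
meaningful while keeping desk-scale burn-in (1,500 iterations) sufficient.
A finiteness check every 500 iterations aborts with a diagnostic dump if the
state ever diverges. Each chain's RNG stream is spawned from the master seed;
identical configuration and seed reproduce chains bit-for-bit.

Default protocol: 2 chains × 10,000 iterations, first 5,000 discarded per
chain, no thinning; the posterior mean is the point estimate. The desk-scale
protocol used by the test suite and the acceptance script is 2 × 3,000 with
1,500 burn-in, which reproduces the full-length recovery values to well within
replication noise (spot checks at 2 × 10,000 agree to three decimals).

## Synthetic-data generator

The generator emulates the structure of PISA-2012-style computer-based
mathematics data: K ∈ {3, 5} content dimensions, balanced between-item
Q-matrices in contiguous blocks of I/K items (the 9-item PISA Q-matrix with
column pattern (2, 4, 3) ships as a fixture), and

* persons from `MVN(0, Σ_person)` with ability variance 1 and covariance 0.8,
  speed variance 0.25 and covariance 0.15 (correlation 0.6), and a constant
  ability–speed cross block `0.5·ρ_θτ`, ρ_θτ ∈ {−0.4, −0.7};
* items `(d_i, ξ_i) ~ BVN((0, 4), [[1, −0.2], [−0.2, 0.25]])` (so
  corr(d, ξ) = −0.4) and ω_i = 2 for every item (residual SD of log T = 0.5);
* Y from the Rasch probabilities, T = exp of the simulated log times, in
  seconds, unrounded.

Person draws are recentered to exact zero column means so that every generated
sample satisfies the identification constraint the fitted model imposes
(μ_θ = μ_τ = 0). This matters for scoring: the realized sample mean of τ_k
(SD = 0.5/√N ≈ 0.022 at N = 500) is not identified separately from the item
locations of dimension k, so without recentering it leaks into ξ̂ and puts a
floor of ≈ 0.022 on the time-intensity RMSE that has nothing to do with
estimation quality.

What the generator does **not** emulate: within-item multidimensionality,
rapid-guessing/aberrant respondents, item-position effects on speed, and
missingness mechanisms (simulated datasets are complete; missing-data handling
is exercised through the IO layer and masked-likelihood tests). Passing
recovery tests on this generator therefore demonstrates correctness of the
estimator under the model's own assumptions, not robustness to their
violation.

## Recovery scoring

Per replication the posterior mean is scored against the generating truth;
bias = mean error, RMSE = root-mean-square error, and Cor is the
within-replication Pearson correlation across entities (items or persons),
averaged over replications. Cor is reported as NA when the truth is constant
(ω ≡ 2). Hyperparameters (μ_d, μ_ξ, variance/covariance elements) are scored
against the **realized sample moments** of that replication's generating
draws: the deviation of realized moments from the nominal design values is
generator sampling noise (e.g. SD ≈ 0.13 for the mean of 15 ξ's), not
estimator error, and would otherwise dominate the item-level-mean rows.
Scores against the nominal values are reported alongside
(`bias_vs_nominal`, `rmse_vs_nominal`). Replication r uses seed
`condition.seed + r`; the sampler runs on a disjoint seed stream.

## Model fit and comparison

* **PSRF** is the classic Gelman–Rubin factor on whole chains,
  `sqrt(((n−1)/n·W + B/n)/W)`; < 1.2 is the convergence line, and undefined
  (zero within-chain variance) is flagged as NaN rather than an error.
* **PPMC** uses two realized discrepancies: the sum of squared Pearson
  residuals of Y (the literal typeset variant without the square on the
  denominator is available behind `typeset_variant=True` for audit) and the
  sum of squared standardized errors of log T. The ppp value is computed over
  evenly spaced retained draws (default 500) — replicate, compare, count.
  Both statistics are mildly conservative (values cluster above 0.5 on
  well-specified data) because posterior draws partially fit the realized
  noise.
* **DIC/WAIC** use per-cell joint log-likelihood components: the "point" is
  the (n, i) cell, combining the Y and log-T terms when both are observed.
  WAIC uses the variance-form penalty; DIC plugs in posterior means of all
  parameters including person parameters. Other pointwise conventions
  (per-person, per-response-type) would shift absolute values, which is why
  empirical information criteria should be compared only within one
  convention.

## Numerical choices

Bernoulli log-masses are computed as `y·η − log1pexp(η)` with a stable
log1pexp; probabilities are clipped away from {0, 1} only at the float
boundary. Posterior-mean covariance matrices are eigenvalue-nudged
(`≥ 1e-10`) before the positive-definiteness check, since averaging draws can
sit numerically on the boundary. Conditional item-prior variances are floored
at 1e-12 against degenerate Σ_item draws. The τ update uses a single shared
precision matrix when no times are missing and batched per-person solves
otherwise.

## Known limitations

* Accuracy is Rasch-form only (no discrimination/guessing parameters), and
  the time model has no time-discrimination slope; both are deliberate scope
  bounds.
* The logistic blocks use random-walk Metropolis rather than an
  auxiliary-variable scheme; mixing is adequate at the study's scales but
  would benefit from augmentation for very large I.
* Desk-scale chains (2 × 3,000) occasionally show a worst-parameter PSRF just
  above 1.2 in a replication; the recovery driver logs these and proceeds.
  Full-length chains sit below 1.1.
* At R = 5 replications the RMSE of a single hyperparameter (e.g. one speed
  variance) carries ≈ 30% relative sampling noise, so individual-cell
  comparisons at that scale should be read accordingly.
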
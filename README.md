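# mmjoint

Joint Bayesian modeling of item response accuracy and response times for
multidimensional tests, where **working speed is allowed to vary across the
ability dimensions** a test measures.

## The problem

Computer-based assessments (PISA-style) log both whether an answer is correct
and how long it took. Hierarchical joint models exploit both, but nearly all of
them assume each respondent works at one constant speed across the whole test.
When items measure different content dimensions (say algebra vs. geometry),
that assumption is too restrictive: a respondent may be fast on one dimension
and slow on another. `mmjoint` implements a joint model in which a confirmatory
Q-matrix drives **both** a multidimensional Rasch model for accuracy and a
multifactor lognormal model for response times.

## The model

For person *n* and item *i*, with a binary Q-matrix `q_ik` mapping each item to
the single dimension it measures (between-item multidimensionality):

```
logit P(Y_ni = 1) = Σ_k θ_nk q_ik + d_i                  (accuracy)
log T_ni ~ Normal(ξ_i − τ̃_ni, ω_i⁻²),  τ̃_ni = Σ_k τ_nk q_ik   (times)
```

* `θ_nk` — latent ability on dimension *k*; `d_i` — item easiness;
* `τ_nk` — working-speed factor attached to dimension *k*; `τ̃_ni` — the
  instantaneous speed applied to item *i*;
* `ξ_i` — time-intensity (how much time the item demands); `ω_i` — time
  precision (reciprocal residual SD of log T).

Persons `(θ_n, τ_n) ~ MVN(0, Σ_person)` (mean fixed at zero for
identification); items `(d_i, ξ_i) ~ BVN((μ_d, μ_ξ), Σ_item)`. Estimation is
full-Bayes MCMC (Metropolis-within-Gibbs: conjugate updates for every Gaussian
/ Gamma / inverse-Wishart block, adaptive random-walk Metropolis for the
logistic blocks, plus exact Gibbs recentering along the weakly identified
location ridges). Nested variants: `msj` (single speed factor) and `slrt`
(times only). Diagnostics: Gelman–Rubin PSRF, posterior predictive checks with
Pearson-residual and standardized-error discrepancies, DIC and WAIC.

## Worked example

```python
import numpy as np
from mmjoint import JointModel, SimulationCondition, simulate_dataset
from mmjoint.diagnostics import fit_report

cond = SimulationCondition(N=200, I=15, K=3, rho_theta_tau=-0.7, seed=1)
data, persons, items = simulate_dataset(cond)

model = JointModel(n_iterations=2000, n_burnin=1000, seed=1).fit(data)
print(model.summary_.loc[["xi[0]", "omega[0]", "sigma_person[0,3]",
                          "sigma_person[3,3]"]].round(3))
```

prints

```
                    mean     sd   q2.5  q97.5
param
xi[0]              4.037  0.055  3.929  4.143
omega[0]           1.788  0.100  1.596  1.983
sigma_person[0,3] -0.410  0.069 -0.560 -0.284
sigma_person[3,3]  0.261  0.032  0.204  0.329
```

The first item's time-intensity is recovered near its generating value
(`ξ ≈ 4` ⇒ typical times around e⁴ ≈ 55 s), the ability–speed covariance
`sigma_person[0,3]` is clearly negative (generated at −0.35: more able
respondents work faster), and the first speed-factor variance
`sigma_person[3,3]` sits near its generating 0.25. Posterior-mean person
parameters track the truth (`cor(τ̂₁, τ₁) = 0.925`, `cor(θ̂₁, θ₁) = 0.880`
here), and

```python
rep = fit_report(data, model.chains_, n_ppp_draws=200)
# ppp_ra=0.435  ppp_rt=0.695  dic=8294  waic=8304
```

shows posterior predictive p-values near 0.5 — no systematic misfit, as
expected for well-specified data.

A command-line toolchain wraps the same pipeline:

```bash
mmjoint simulate --N 500 --I 15 --K 3 --rho -0.4 --seed 1 --out sim/
mmjoint fit --responses sim/Y_1.csv --times sim/T_1.csv --qmatrix sim/Q.csv \
            --chains 2 --iter 10000 --burnin 5000 --seed 2 --out fit/chains.npz
mmjoint diagnose --chains fit/chains.npz --responses sim/Y_1.csv \
                 --times sim/T_1.csv --qmatrix sim/Q.csv --out report.json
mmjoint compare --models mmj,msj --responses sim/Y_1.csv --times sim/T_1.csv \
                --qmatrix sim/Q.csv --out comparison.csv
```

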
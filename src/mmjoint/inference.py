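"""Full Bayesian MCMC estimation of the joint model.

Sampling scheme (Metropolis-within-Gibbs, one sweep per iteration):

* ability vectors theta_n and easiness d_i enter the likelihood through
  a logistic link and are updated by vectorized adaptive random-walk
  Metropolis (scale tuned toward a target acceptance rate during
  burn-in, frozen afterwards);
* speed vectors tau_n, time-intensity xi_i, time precision omega_i^2,
  the person covariance Sigma_person, and the item-level
  (mu_d, mu_xi, Sigma_item) all have closed-form conjugate conditionals
  (Gaussian, Gamma, inverse-Wishart) and are Gibbs-updated exactly;
* the person-level mean is fixed at zero for identification and never
  sampled.

Priors follow the weakly informative hierarchical setup:
Sigma_person ~ InvWishart(identity, df = dimension), (d_i, xi_i) ~
BVN((mu_d, mu_xi), Sigma_item) with mu_d ~ Normal(0, .), mu_xi ~
Normal(4.3, .), Sigma_item ~ InvWishart(identity_2, 2), and
omega_i^-2 ~ InvGamma(1, 1).  The second argument of the Normal
hyperpriors is interpreted as a variance by default (the reading
consistent with recovery of the item-level means at short test lengths,
where a precision-2 prior would visibly over-shrink them); set
``hyperprior_scale_is="precision"`` for the BUGS/JAGS-style reading.

Model variants:

* ``mmj``  - multidimensional ability, multifactor speed (speed Q-matrix
  equals the ability Q-matrix);
* ``msj``  - multidimensional ability, single speed factor (speed
  Q-matrix is a single all-ones column);
* ``slrt`` - response times only, single speed factor (no accuracy part).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    ItemParams,
    JointDataset,
    PersonParams,
    PopulationStructure,
    QMatrix,
    bernoulli_logmass,
    joint_loglik,
    log1pexp,
)

__all__ = [
    "SamplerConfig",
    "PriorSpec",
    "PosteriorChains",
    "JointModel",
    "run_mcmc",
    "fit_msj",
    "posterior_summary",
]

_VARIANTS = ("mmj", "msj", "slrt")


@dataclass
class SamplerConfig:
    """Chain protocol: 2 chains x 10,000 iterations, first 5,000 burn-in."""

    n_chains: int = 2
    n_iterations: int = 10000
    n_burnin: int = 5000
    seed: int = 0
    model_variant: str = "mmj"
    thinning: int = 1
    target_accept: float = 0.35
    init_jitter: float = 0.5
    verbose: int = 0

    def __post_init__(self):
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("need 0 <= n_burnin < n_iterations")
        if self.model_variant not in _VARIANTS:
            raise ValueError(f"model_variant must be one of {_VARIANTS}")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_chains < 2:
            warnings.warn("PSRF requires >= 2 chains", stacklevel=2)
        if not 0.05 < self.target_accept < 0.95:
            raise ValueError("target_accept out of range")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thinning


@dataclass
class PriorSpec:
    """Hyperprior settings; ``None`` scale/df fields resolve to the
    identity / dimension defaults at fit time."""

    person_scale: np.ndarray | None = None
    person_df: float | None = None
    item_scale: np.ndarray | None = None
    item_df: float | None = None
    mu_d_mean: float = 0.0
    mu_xi_mean: float = 4.3
    hyper_mu_spread: float = 2.0
    hyperprior_scale_is: str = "variance"
    omega2_shape: float = 1.0
    omega2_rate: float = 1.0

    def __post_init__(self):
        if self.hyperprior_scale_is not in ("precision", "variance"):
            raise ValueError("hyperprior_scale_is must be 'precision' or 'variance'")
        if self.omega2_shape <= 0 or self.omega2_rate <= 0:
            raise ValueError("omega precision prior parameters must be positive")

    @property
    def hyper_mu_var(self) -> float:
        s = self.hyper_mu_spread
        return 1.0 / s if self.hyperprior_scale_is == "precision" else s

    def resolve(self, person_dim: int, item_dim: int):
        Rp = np.eye(person_dim) if self.person_scale is None else np.asarray(self.person_scale, float)
        dfp = float(person_dim) if self.person_df is None else float(self.person_df)
        Ri = np.eye(item_dim) if self.item_scale is None else np.asarray(self.item_scale, float)
        dfi = float(item_dim) if self.item_df is None else float(self.item_df)
        if dfp < person_dim or dfi < item_dim:
            raise ValueError("inverse-Wishart df must be >= dimension")
        for M, name in ((Rp, "person_scale"), (Ri, "item_scale")):
            if np.linalg.eigvalsh(M).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        return Rp, dfp, Ri, dfi


@dataclass
class PosteriorChains:
    """Retained MCMC draws with chain/draw leading axes plus metadata."""

    draws: dict[str, np.ndarray]
    variant: str
    q_ability: np.ndarray | None
    q_speed: np.ndarray
    config: dict
    seeds: list[int]
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        shapes = {k: v.shape[:2] for k, v in self.draws.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"inconsistent chain/draw axes: {shapes}")
        om = self.draws.get("omega")
        if om is not None and (om <= 0).any():
            raise ValueError("all omega draws must be positive")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws with chain and draw axes merged."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def posterior_mean(self, name: str) -> np.ndarray:
        return self.pooled(name).mean(axis=0)

    def scalar_draws(self, include_persons: bool = False) -> dict[str, np.ndarray]:
        """Flatten every retained parameter into named (chain, draw) series."""
        out: dict[str, np.ndarray] = {}
        person_keys = {"theta", "tau"}
        for name, arr in self.draws.items():
            if not include_persons and name in person_keys:
                continue
            if arr.ndim == 2:
                out[name] = arr
            elif arr.ndim == 3:
                for j in range(arr.shape[2]):
                    out[f"{name}[{j}]"] = arr[:, :, j]
            elif arr.ndim == 4 and name in ("sigma_person", "sigma_item"):
                p = arr.shape[2]
                for a in range(p):
                    for b in range(a, p):
                        out[f"{name}[{a},{b}]"] = arr[:, :, a, b]
            elif arr.ndim == 4:
                for a in range(arr.shape[2]):
                    for b in range(arr.shape[3]):
                        out[f"{name}[{a},{b}]"] = arr[:, :, a, b]
        return out

    def mean_person_params(self) -> PersonParams:
        return PersonParams(
            theta=self.posterior_mean("theta") if "theta" in self.draws
            else np.zeros_like(self.posterior_mean("tau")),
            tau=self.posterior_mean("tau"),
        )

    def mean_item_params(self) -> ItemParams:
        xi = self.posterior_mean("xi")
        d = self.posterior_mean("d") if "d" in self.draws else np.zeros_like(xi)
        return ItemParams(d=d, xi=xi, omega=self.posterior_mean("omega"))


def posterior_summary(chains: PosteriorChains,
                      include_persons: bool = False) -> pd.DataFrame:
    """Posterior mean (the point estimate), SD and central 95% interval
    for every scalar parameter."""
    rows = []
    for name, arr in chains.scalar_draws(include_persons=include_persons).items():
        flat = arr.reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append((name, flat.mean(), flat.std(ddof=0), lo, hi))
    return pd.DataFrame(rows, columns=["param", "mean", "sd", "q2.5", "q97.5"]).set_index("param")


# --------------------------------------------------------------------------
# sampler internals


def _sample_invwishart(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return sps.invwishart.rvs(df=df, scale=scale, random_state=rng)


def _conditional_gaussian(sigma: np.ndarray, k: int):
    """Partition an MVN covariance into first-k vs rest; return the
    regression matrix and conditional covariance of the REST given the
    first block (mean = M @ x_first)."""
    if k == 0:
        return np.zeros((sigma.shape[0], 0)), sigma.copy()
    A = sigma[:k, :k]
    B = sigma[:k, k:]
    C = sigma[k:, k:]
    Ainv_B = np.linalg.solve(A, B)
    M = Ainv_B.T                      # rest | first: mean M @ x_first
    V = C - B.T @ Ainv_B
    return M, V


class _ChainState:
    __slots__ = ("theta", "tau", "d", "xi", "omega2", "sigma_person",
                 "mu_item", "sigma_item", "G", "s_theta", "s_d",
                 "acc_theta", "acc_d", "n_acc_steps")

    def __init__(self):
        self.acc_theta = 0.0
        self.acc_d = 0.0
        self.n_acc_steps = 0


class JointModel:
    """Joint Bayesian model of item responses and response times.

    Scikit-learn-style estimator: configure in ``__init__``, call
    :meth:`fit` with a :class:`~mmjoint.core.JointDataset`, read the
    posterior from trailing-underscore attributes (``chains_``,
    ``item_params_``, ``person_params_``, ``population_``,
    ``summary_``).

    Parameters
    ----------
    variant : {"mmj", "msj", "slrt"}
        Multifactor speed, single-factor speed, or times-only model.
    n_chains, n_iterations, n_burnin, thinning, seed
        Chain protocol; the retained sample pools all chains after
        discarding burn-in per chain.
    target_accept : float
        Acceptance rate targeted by the Metropolis scale adaptation for
        the logistic (theta, d) blocks.
    priors : PriorSpec, optional
    fixed : dict, optional
        Parameter blocks to hold at given values instead of sampling
        (testing / degenerate-model hook), e.g. ``{"sigma_person": S}``.
    """

    def __init__(self, variant: str = "mmj", n_chains: int = 2,
                 n_iterations: int = 10000, n_burnin: int = 5000,
                 thinning: int = 1, seed: int = 0,
                 target_accept: float = 0.35, init_jitter: float = 0.5,
                 priors: PriorSpec | None = None, fixed: dict | None = None,
                 verbose: int = 0):
        self.variant = variant
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.n_burnin = n_burnin
        self.thinning = thinning
        self.seed = seed
        self.target_accept = target_accept
        self.init_jitter = init_jitter
        self.priors = priors
        self.fixed = fixed
        self.verbose = verbose

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "variant", "n_chains", "n_iterations", "n_burnin", "thinning",
            "seed", "target_accept", "init_jitter", "priors", "fixed", "verbose")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def __repr__(self):
        return (f"JointModel(variant={self.variant!r}, n_chains={self.n_chains}, "
                f"n_iterations={self.n_iterations}, n_burnin={self.n_burnin})")

    # -- fitting ------------------------------------------------------------
    def _config(self) -> SamplerConfig:
        return SamplerConfig(
            n_chains=self.n_chains, n_iterations=self.n_iterations,
            n_burnin=self.n_burnin, seed=self.seed,
            model_variant=self.variant, thinning=self.thinning,
            target_accept=self.target_accept, init_jitter=self.init_jitter,
            verbose=self.verbose)

    def fit(self, data: JointDataset, y=None):
        cfg = self._config()
        priors = self.priors if self.priors is not None else PriorSpec()
        fixed = self.fixed or {}
        variant = cfg.model_variant

        Qa = data.q.entries.astype(float)
        K = data.q.n_dims
        if variant == "mmj":
            Qs = Qa
        else:
            Qs = np.ones((data.n_items, 1))
        has_accuracy = variant != "slrt"
        Ka = K if has_accuracy else 0
        Ks = Qs.shape[1]
        P = Ka + Ks
        item_dim = 2 if has_accuracy else 1
        Rp, dfp, Ri, dfi = priors.resolve(P, item_dim)

        ss = np.random.SeedSequence(cfg.seed)
        chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.n_chains)]

        stores = []
        acc_theta, acc_d = [], []
        for c in range(cfg.n_chains):
            rng = np.random.default_rng(chain_seeds[c])
            store, at, ad = self._run_chain(
                data, cfg, priors, fixed, rng,
                Qa if has_accuracy else None, Qs, Rp, dfp, Ri, dfi)
            stores.append(store)
            acc_theta.append(at)
            acc_d.append(ad)

        draws = {k: np.stack([s[k] for s in stores]) for k in stores[0]}
        acceptance = {}
        if has_accuracy:
            acceptance["theta"] = float(np.mean(acc_theta))
            acceptance["d"] = float(np.mean(acc_d))
        self.chains_ = PosteriorChains(
            draws=draws, variant=variant,
            q_ability=data.q.entries.copy() if has_accuracy else None,
            q_speed=Qs.astype(np.int8),
            config={
                "n_chains": cfg.n_chains, "n_iterations": cfg.n_iterations,
                "n_burnin": cfg.n_burnin, "thinning": cfg.thinning,
                "seed": cfg.seed, "model_variant": variant,
                "target_accept": cfg.target_accept,
                "hyperprior_scale_is": priors.hyperprior_scale_is,
            },
            seeds=chain_seeds, acceptance=acceptance)
        ch = self.chains_
        self.person_params_ = ch.mean_person_params()
        self.item_params_ = ch.mean_item_params()
        self.population_ = PopulationStructure(
            sigma_person=_nearest_pd(ch.posterior_mean("sigma_person")),
            mu_item=ch.posterior_mean("mu_item"),
            sigma_item=_nearest_pd(ch.posterior_mean("sigma_item")),
        )
        self.summary_ = posterior_summary(ch)
        return self

    # -- one chain ----------------------------------------------------------
    def _run_chain(self, data: JointDataset, cfg: SamplerConfig,
                   priors: PriorSpec, fixed: dict, rng: np.random.Generator,
                   Qa, Qs, Rp, dfp, Ri, dfi):
        N, I = data.n_persons, data.n_items
        has_acc = Qa is not None
        Ka = Qa.shape[1] if has_acc else 0
        Ks = Qs.shape[1]
        P = Ka + Ks
        item_dim = 2 if has_acc else 1
        MT = data.mask_t
        Y0, logT = data.Y0, data.logT
        full_t = bool(MT.all())
        nt_i = MT.sum(axis=0).astype(float)            # observed times per item
        mu0 = np.array([priors.mu_d_mean, priors.mu_xi_mean]) if has_acc \
            else np.array([priors.mu_xi_mean])
        V0 = np.eye(item_dim) * priors.hyper_mu_var

        st = self._init_state(data, rng, cfg, has_acc, Ka, Ks, P, item_dim, fixed)

        n_draws = cfg.n_draws
        store = {
            "tau": np.empty((n_draws, N, Ks)),
            "xi": np.empty((n_draws, I)),
            "omega": np.empty((n_draws, I)),
            "sigma_person": np.empty((n_draws, P, P)),
            "mu_item": np.empty((n_draws, item_dim)),
            "sigma_item": np.empty((n_draws, item_dim, item_dim)),
        }
        if has_acc:
            store["theta"] = np.empty((n_draws, N, Ka))
            store["d"] = np.empty((n_draws, I))

        acc_theta_sum = acc_d_sum = 0.0
        n_post = 0
        idx = 0
        for it in range(cfg.n_iterations):
            in_burn = it < cfg.n_burnin
            gamma = (it + 1) ** -0.6 if in_burn else 0.0

            if has_acc:
                M_th, V_th = _conditional_gaussian(
                    _swap_blocks(st.sigma_person, Ka), Ks)  # theta | tau
                a = self._update_theta(st, data, Qa, M_th, V_th, rng, gamma, cfg, fixed)
                if not in_burn:
                    acc_theta_sum += a
            M_ta, V_ta = _conditional_gaussian(st.sigma_person, Ka)  # tau | theta
            self._update_tau(st, data, Qs, M_ta, V_ta, rng, full_t, fixed)
            if has_acc:
                a = self._update_d(st, data, rng, gamma, cfg, fixed)
                if not in_burn:
                    acc_d_sum += a
            self._update_xi(st, data, Qs, nt_i, rng, has_acc, fixed)
            self._update_shifts(st, Qa, Qs, rng, has_acc, fixed)
            self._update_omega2(st, data, Qs, nt_i, priors, rng, fixed)
            self._update_sigma_person(st, Rp, dfp, N, rng, has_acc, fixed)
            self._update_item_hyper(st, Ri, dfi, mu0, V0, I, rng, has_acc, fixed)
            if not in_burn:
                n_post += 1

            if (it + 1) % 500 == 0:
                self._check_finite(st, it)
                if cfg.verbose:
                    ll = self._total_loglik(st, data, Qa, Qs)
                    print(f"iter {it + 1}: loglik={ll:.1f} "
                          f"s_theta={st.s_theta:.3f} s_d={st.s_d:.3f}")

            if not in_burn and (it - cfg.n_burnin) % cfg.thinning == 0 and idx < n_draws:
                store["tau"][idx] = st.tau
                store["xi"][idx] = st.xi
                store["omega"][idx] = np.sqrt(st.omega2)
                store["sigma_person"][idx] = st.sigma_person
                store["mu_item"][idx] = st.mu_item
                store["sigma_item"][idx] = st.sigma_item
                if has_acc:
                    store["theta"][idx] = st.theta
                    store["d"][idx] = st.d
                idx += 1

        at = acc_theta_sum / max(n_post, 1)
        ad = acc_d_sum / max(n_post, 1)
        return store, at, ad

    def _init_state(self, data, rng, cfg, has_acc, Ka, Ks, P, item_dim, fixed):
        st = _ChainState()
        N, I = data.n_persons, data.n_items
        j = cfg.init_jitter
        with np.errstate(invalid="ignore"):
            pbar = np.where(data.mask_y.any(axis=0),
                            data.Y0.sum(axis=0) / np.maximum(data.mask_y.sum(axis=0), 1),
                            0.5)
        pbar = np.clip(pbar, 0.05, 0.95)
        lt_mean = np.where(data.mask_t.any(axis=0),
                           data.logT.sum(axis=0) / np.maximum(data.mask_t.sum(axis=0), 1),
                           4.0)
        st.xi = lt_mean + rng.normal(0, 0.2 * j + 1e-12, I)
        st.omega2 = np.full(I, 2.0) * np.exp(rng.normal(0, 0.2 * j + 1e-12, I))
        st.tau = rng.normal(0, 0.3 * j + 1e-3, (N, Ks))
        st.sigma_person = np.eye(P)
        if has_acc:
            st.d = np.log(pbar / (1 - pbar)) + rng.normal(0, 0.5 * j + 1e-12, I)
            st.theta = rng.normal(0, max(j, 0.1), (N, Ka))
            st.mu_item = np.array([float(st.d.mean()), float(st.xi.mean())])
            st.sigma_item = np.diag([max(float(st.d.var()), 0.2),
                                     max(float(st.xi.var()), 0.05)])
            st.G = st.theta @ data.q.entries.astype(float).T
        else:
            st.theta = np.zeros((N, 0))
            st.d = None
            st.mu_item = np.array([float(st.xi.mean())])
            st.sigma_item = np.array([[max(float(st.xi.var()), 0.05)]])
            st.G = None
        st.s_theta = 0.8
        st.s_d = 0.25
        for k, v in fixed.items():
            if k == "omega":
                st.omega2 = np.asarray(v, float) ** 2
            elif hasattr(st, k):
                setattr(st, k, np.asarray(v, float).copy())
        if has_acc and "theta" in fixed:
            st.G = st.theta @ data.q.entries.astype(float).T
        return st

    # individual updates ----------------------------------------------------
    def _update_theta(self, st, data, Qa, M, V, rng, gamma, cfg, fixed):
        if "theta" in fixed:
            return 1.0
        N, Ka = st.theta.shape
        Vinv = np.linalg.inv(V)
        mean = st.tau @ M.T                       # N x Ka conditional prior mean
        prop = st.theta + st.s_theta * rng.standard_normal((N, Ka))
        Gp = prop @ Qa.T
        eta_cur = st.G + st.d
        eta_prop = Gp + st.d
        ll_cur = np.where(data.mask_y, data.Y0 * eta_cur - log1pexp(eta_cur), 0.0).sum(axis=1)
        ll_prop = np.where(data.mask_y, data.Y0 * eta_prop - log1pexp(eta_prop), 0.0).sum(axis=1)
        dc = st.theta - mean
        dp = prop - mean
        lp_cur = -0.5 * np.einsum("nk,kl,nl->n", dc, Vinv, dc)
        lp_prop = -0.5 * np.einsum("nk,kl,nl->n", dp, Vinv, dp)
        log_alpha = (ll_prop + lp_prop) - (ll_cur + lp_cur)
        acc = np.log(rng.random(N)) < log_alpha
        st.theta = np.where(acc[:, None], prop, st.theta)
        st.G = np.where(acc[:, None], Gp, st.G)
        rate = float(acc.mean())
        if gamma > 0:
            st.s_theta *= float(np.exp(gamma * (rate - cfg.target_accept)))
        return rate

    def _update_tau(self, st, data, Qs, M, V, rng, full_t, fixed):
        if "tau" in fixed:
            return
        N, Ks = st.tau.shape
        Vinv = np.linalg.inv(V)
        prior_mean = st.theta @ M.T if st.theta.shape[1] else np.zeros((N, Ks))
        wq = st.omega2[:, None] * Qs              # I x Ks
        resid = st.xi[None, :] - data.logT        # target for q.tau
        if full_t:
            A = wq.sum(axis=0)                    # same diag for every person
            b = resid @ wq
            prec = Vinv + np.diag(A)
            cov = np.linalg.inv(prec)
            L = np.linalg.cholesky(cov)
            mean = (prior_mean @ Vinv.T + b) @ cov.T
            st.tau = mean + rng.standard_normal((N, Ks)) @ L.T
        else:
            A = data.mask_t @ wq                  # N x Ks
            b = (np.where(data.mask_t, resid, 0.0)) @ wq
            prec = Vinv[None, :, :] + A[:, :, None] * np.eye(Ks)[None, :, :]
            cov = np.linalg.inv(prec)
            L = np.linalg.cholesky(cov)
            rhs = prior_mean @ Vinv.T + b
            mean = np.einsum("nkl,nl->nk", cov, rhs)
            z = rng.standard_normal((N, Ks))
            st.tau = mean + np.einsum("nkl,nl->nk", L, z)

    def _update_d(self, st, data, rng, gamma, cfg, fixed):
        if "d" in fixed:
            return 1.0
        I = st.d.shape[0]
        mu_d, mu_xi = st.mu_item
        s2d, sdx, s2x = st.sigma_item[0, 0], st.sigma_item[0, 1], st.sigma_item[1, 1]
        cond_mean = mu_d + (sdx / s2x) * (st.xi - mu_xi)
        cond_var = max(s2d - sdx**2 / s2x, 1e-12)
        prop = st.d + st.s_d * rng.standard_normal(I)
        eta_cur = st.G + st.d
        eta_prop = st.G + prop
        ll_cur = np.where(data.mask_y, data.Y0 * eta_cur - log1pexp(eta_cur), 0.0).sum(axis=0)
        ll_prop = np.where(data.mask_y, data.Y0 * eta_prop - log1pexp(eta_prop), 0.0).sum(axis=0)
        lp_cur = -0.5 * (st.d - cond_mean) ** 2 / cond_var
        lp_prop = -0.5 * (prop - cond_mean) ** 2 / cond_var
        acc = np.log(rng.random(I)) < (ll_prop + lp_prop) - (ll_cur + lp_cur)
        st.d = np.where(acc, prop, st.d)
        rate = float(acc.mean())
        if gamma > 0:
            st.s_d *= float(np.exp(gamma * (rate - cfg.target_accept)))
        return rate

    def _update_xi(self, st, data, Qs, nt_i, rng, has_acc, fixed):
        if "xi" in fixed:
            return
        if has_acc:
            mu_d, mu_xi = st.mu_item
            s2d, sdx, s2x = st.sigma_item[0, 0], st.sigma_item[0, 1], st.sigma_item[1, 1]
            m0 = mu_xi + (sdx / s2d) * (st.d - mu_d)
            v0 = max(s2x - sdx**2 / s2d, 1e-12)
        else:
            m0 = np.full_like(st.xi, st.mu_item[0])
            v0 = max(st.sigma_item[0, 0], 1e-12)
        tau_tilde = st.tau @ Qs.T                 # N x I
        S = np.where(data.mask_t, data.logT + tau_tilde, 0.0).sum(axis=0)
        prec = 1.0 / v0 + st.omega2 * nt_i
        mean = (m0 / v0 + st.omega2 * S) / prec
        st.xi = mean + rng.standard_normal(st.xi.shape[0]) / np.sqrt(prec)

    def _update_shifts(self, st, Qa, Qs, rng, has_acc, fixed):
        """Exact Gibbs moves along the weakly identified location ridges.

        Adding a constant to every person's theta_k while subtracting it
        from the easiness of the items measuring dimension k leaves the
        likelihood unchanged (same for tau_k and time-intensity with the
        opposite sign), so the conditional posterior of the shift is the
        Gaussian determined by the person and item priors alone.
        Sampling it exactly removes the slow random-walk mixing of the
        item-location parameters.
        """
        N = st.tau.shape[0]
        Ka = st.theta.shape[1]
        Ks = st.tau.shape[1]
        Sp_inv = np.linalg.inv(st.sigma_person)
        A = np.linalg.inv(st.sigma_item)
        do_ability = has_acc and "theta" not in fixed and "d" not in fixed
        do_speed = "tau" not in fixed and "xi" not in fixed
        if do_ability:
            for k in range(Ka):
                items_k = np.flatnonzero(Qa[:, k] == 1)
                if len(items_k) == 0:
                    continue
                W_sum = np.concatenate([st.theta.sum(axis=0), st.tau.sum(axis=0)])
                Sx = (np.column_stack([st.d, st.xi])[items_k] - st.mu_item).sum(axis=0)
                prec = N * Sp_inv[k, k] + len(items_k) * A[0, 0]
                b = -(Sp_inv[k] @ W_sum) + (A[0] @ Sx)
                delta = b / prec + rng.standard_normal() / np.sqrt(prec)
                st.theta[:, k] += delta
                st.d[items_k] -= delta
                st.G[:, items_k] += delta
        if do_speed:
            X = np.column_stack([st.d, st.xi]) if has_acc else st.xi[:, None]
            v = A.shape[0] - 1  # xi row of the item precision
            for k in range(Ks):
                items_k = np.flatnonzero(Qs[:, k] == 1)
                if len(items_k) == 0:
                    continue
                j = Ka + k
                W_sum = (np.concatenate([st.theta.sum(axis=0), st.tau.sum(axis=0)])
                         if has_acc else st.tau.sum(axis=0))
                X = np.column_stack([st.d, st.xi]) if has_acc else st.xi[:, None]
                Sx = (X[items_k] - st.mu_item).sum(axis=0)
                prec = N * Sp_inv[j, j] + len(items_k) * A[v, v]
                b = -(Sp_inv[j] @ W_sum) - (A[v] @ Sx)
                delta = b / prec + rng.standard_normal() / np.sqrt(prec)
                st.tau[:, k] += delta
                st.xi[items_k] += delta

    def _update_omega2(self, st, data, Qs, nt_i, priors, rng, fixed):
        if "omega" in fixed or "omega2" in fixed:
            return
        tau_tilde = st.tau @ Qs.T
        res = data.logT - (st.xi[None, :] - tau_tilde)
        ss = np.where(data.mask_t, res * res, 0.0).sum(axis=0)
        shape = priors.omega2_shape + 0.5 * nt_i
        rate = priors.omega2_rate + 0.5 * ss
        st.omega2 = rng.gamma(shape, 1.0 / rate)

    def _update_sigma_person(self, st, Rp, dfp, N, rng, has_acc, fixed):
        if "sigma_person" in fixed:
            return
        W = np.hstack([st.theta, st.tau]) if has_acc else st.tau
        S = Rp + W.T @ W
        st.sigma_person = _sample_invwishart(dfp + N, S, rng)
        if st.sigma_person.ndim == 0:             # 1x1 case
            st.sigma_person = np.array([[float(st.sigma_person)]])

    def _update_item_hyper(self, st, Ri, dfi, mu0, V0, I, rng, has_acc, fixed):
        X = np.column_stack([st.d, st.xi]) if has_acc else st.xi[:, None]
        if "mu_item" not in fixed:
            Sinv = np.linalg.inv(st.sigma_item)
            prec = np.linalg.inv(V0) + I * Sinv
            cov = np.linalg.inv(prec)
            mean = cov @ (np.linalg.solve(V0, mu0) + Sinv @ X.sum(axis=0))
            st.mu_item = rng.multivariate_normal(mean, cov, method="cholesky")
        if "sigma_item" not in fixed:
            dev = X - st.mu_item
            S = Ri + dev.T @ dev
            sig = _sample_invwishart(dfi + I, S, rng)
            st.sigma_item = np.atleast_2d(sig)

    def _total_loglik(self, st, data, Qa, Qs):
        persons = PersonParams(theta=st.theta if st.theta.shape[1] else np.zeros_like(st.tau),
                               tau=st.tau)
        items = ItemParams(d=st.d if st.d is not None else np.zeros_like(st.xi),
                           xi=st.xi, omega=np.sqrt(st.omega2))
        eta = (st.G + st.d) if Qa is not None else None
        mu_t = st.xi - st.tau @ Qs.T
        z = np.sqrt(st.omega2) * (data.logT - mu_t)
        t_terms = np.where(data.mask_t,
                           0.5 * np.log(st.omega2) - 0.5 * np.log(2 * np.pi) - 0.5 * z * z, 0.0)
        total = float(t_terms.sum())
        if eta is not None:
            total += float(np.where(data.mask_y, data.Y0 * eta - log1pexp(eta), 0.0).sum())
        return total

    def _check_finite(self, st, it):
        for name in ("theta", "tau", "xi", "omega2", "sigma_person", "mu_item", "sigma_item"):
            v = getattr(st, name)
            if v is not None and not np.isfinite(v).all():
                raise RuntimeError(
                    f"divergent state at iteration {it}: non-finite {name}; "
                    f"state dump: {{'{name}': {np.asarray(v).ravel()[:8]}}}")
        if st.d is not None and not np.isfinite(st.d).all():
            raise RuntimeError(f"divergent state at iteration {it}: non-finite d")


def _swap_blocks(sigma: np.ndarray, Ka: int) -> np.ndarray:
    """Reorder (theta, tau) covariance to (tau, theta)."""
    P = sigma.shape[0]
    order = np.r_[np.arange(Ka, P), np.arange(Ka)]
    return sigma[np.ix_(order, order)]


def _nearest_pd(m: np.ndarray) -> np.ndarray:
    """Symmetrize and nudge eigenvalues so posterior-mean covariances
    always pass the positive-definite check."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    if w.min() <= 1e-10:
        w = np.clip(w, 1e-10, None)
        m = (v * w) @ v.T
        m = 0.5 * (m + m.T)
    return m


def run_mcmc(data: JointDataset, config: SamplerConfig | None = None,
             priors: PriorSpec | None = None, fixed: dict | None = None) -> PosteriorChains:
    """Functional wrapper over :class:`JointModel`."""
    cfg = config or SamplerConfig()
    model = JointModel(
        variant=cfg.model_variant, n_chains=cfg.n_chains,
        n_iterations=cfg.n_iterations, n_burnin=cfg.n_burnin,
        thinning=cfg.thinning, seed=cfg.seed, target_accept=cfg.target_accept,
        init_jitter=cfg.init_jitter, priors=priors, fixed=fixed,
        verbose=cfg.verbose)
    model.fit(data)
    return model.chains_


def fit_msj(data: JointDataset, config: SamplerConfig | None = None,
            priors: PriorSpec | None = None) -> PosteriorChains:
    """Fit the single-speed-factor variant (speed Q-matrix = all-ones column)."""
    cfg = config or SamplerConfig()
    cfg = SamplerConfig(**{**cfg.__dict__, "model_variant": "msj"})
    return run_mcmc(data, cfg, priors)
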
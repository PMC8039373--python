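"""Synthetic data from the joint generating process.

The generator reproduces the design of the model's recovery study:
between-item Q-matrices in balanced contiguous blocks, person parameters
(theta, tau) drawn from a structured multivariate normal with negative
ability-speed correlations, item parameters (d, xi) from a bivariate
normal with mean (0, 4) and covariance [[1, -0.2], [-0.2, 0.25]]
(so corr(d, xi) = -0.4), time precision omega = 2 for all items,
Bernoulli responses from the multidimensional Rasch model, and lognormal
response times.  It emulates the structure of computer-based mathematics
assessment data (PISA-2012-like): a small number of content dimensions,
each measured by a handful of items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ItemParams, JointDataset, PersonParams, QMatrix, mr_prob

__all__ = [
    "SimulationCondition",
    "build_between_item_q",
    "person_covariance",
    "simulate_items",
    "simulate_persons",
    "simulate_dataset",
    "pisa_q_fixture",
]


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design.

    Defaults are the study conditions: ability variance 1 with
    between-ability covariance 0.8, speed-factor variance 0.25 with
    between-speed covariance 0.15 (correlation 0.6), a constant
    ability-speed cross covariance 0.5*rho_theta_tau, item parameters
    (d, xi) ~ BVN((0, 4), [[1, -0.2], [-0.2, 0.25]]), and omega = 2.
    """

    N: int = 500
    I: int = 15
    K: int = 3
    rho_theta_tau: float = -0.4
    rho_theta_theta: float = 0.8
    rho_tau_tau: float = 0.6
    var_theta: float = 1.0
    var_tau: float = 0.25
    item_mu: tuple[float, float] = (0.0, 4.0)
    item_cov: tuple = ((1.0, -0.2), (-0.2, 0.25))
    omega_true: float = 2.0
    n_replications: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.N, self.I, self.K) < 1:
            raise ValueError("N, I, K must be positive")
        if self.var_theta <= 0 or self.var_tau <= 0:
            raise ValueError("variances must be positive")
        if self.omega_true <= 0:
            raise ValueError("omega_true must be positive")
        sigma = person_covariance(self)  # raises if not positive definite
        assert sigma.shape == (2 * self.K, 2 * self.K)


def build_between_item_q(I: int, K: int) -> QMatrix:
    """Balanced between-item Q-matrix: contiguous blocks of I/K items."""
    if I % K != 0:
        raise ValueError(
            f"I={I} not divisible by K={K}: unsupported balanced design"
        )
    block = I // K
    entries = np.zeros((I, K), dtype=np.int8)
    for k in range(K):
        entries[k * block:(k + 1) * block, k] = 1
    return QMatrix(entries)


def person_covariance(condition: SimulationCondition) -> np.ndarray:
    """2K x 2K person covariance (theta block, tau block, constant cross block)."""
    K = condition.K
    vt, vu = condition.var_theta, condition.var_tau
    theta_block = np.full((K, K), condition.rho_theta_theta * vt)
    np.fill_diagonal(theta_block, vt)
    tau_block = np.full((K, K), condition.rho_tau_tau * vu)
    np.fill_diagonal(tau_block, vu)
    # the design fills the entire cross block with a constant
    # rho_theta_tau * sigma_theta * sigma_tau (= 0.5*rho at the default scales)
    cross = np.full((K, K), condition.rho_theta_tau * np.sqrt(vt * vu))
    sigma = np.block([[theta_block, cross], [cross.T, tau_block]])
    if np.linalg.eigvalsh(sigma).min() <= 0:
        raise ValueError("implied person covariance is not positive definite")
    return sigma


def single_speed_person_covariance(condition: SimulationCondition) -> np.ndarray:
    """(K+1) x (K+1) person covariance for the single-speed-factor
    generating process: usual ability block, one speed factor with the
    same variance and ability-speed cross covariance."""
    K = condition.K
    vt, vu = condition.var_theta, condition.var_tau
    theta_block = np.full((K, K), condition.rho_theta_theta * vt)
    np.fill_diagonal(theta_block, vt)
    cross = np.full((K, 1), condition.rho_theta_tau * np.sqrt(vt * vu))
    sigma = np.block([[theta_block, cross], [cross.T, np.array([[vu]])]])
    if np.linalg.eigvalsh(sigma).min() <= 0:
        raise ValueError("implied person covariance is not positive definite")
    return sigma


def simulate_persons(condition: SimulationCondition, rng: np.random.Generator,
                     speed_factors: str = "multifactor",
                     center: bool = True) -> PersonParams:
    """Draw person parameters from MVN(0, Sigma_person).

    With ``center=True`` (default) each column is recentered to exact
    zero mean so every generated sample satisfies the identification
    constraint mu_theta = mu_tau = 0 the fitted model imposes; without
    it, the realized sample means (SD sigma/sqrt(N)) are unidentified
    from item-location shifts and leak into the item-parameter and
    hyper-mean recovery scores.
    """
    if speed_factors == "multifactor":
        sigma = person_covariance(condition)
    elif speed_factors == "single":
        sigma = single_speed_person_covariance(condition)
    else:
        raise ValueError("speed_factors must be 'multifactor' or 'single'")
    draws = rng.multivariate_normal(
        np.zeros(sigma.shape[0]), sigma, size=condition.N, method="cholesky"
    )
    if center:
        draws = draws - draws.mean(axis=0)
    return PersonParams(theta=draws[:, : condition.K], tau=draws[:, condition.K:])


def simulate_items(condition: SimulationCondition, rng: np.random.Generator) -> ItemParams:
    mu = np.asarray(condition.item_mu, dtype=float)
    cov = np.asarray(condition.item_cov, dtype=float)
    dxi = rng.multivariate_normal(mu, cov, size=condition.I, method="cholesky")
    omega = np.full(condition.I, condition.omega_true)
    return ItemParams(d=dxi[:, 0], xi=dxi[:, 1], omega=omega)


def simulate_responses(persons: PersonParams, items: ItemParams, q: QMatrix,
                       rng: np.random.Generator,
                       q_speed: QMatrix | None = None):
    """Bernoulli responses and lognormal times given all parameters."""
    Qa = q.entries.astype(float)
    Qs = Qa if q_speed is None else q_speed.entries.astype(float)
    p = mr_prob(persons.theta[:, None, :], items.d, Qa[None, :, :])
    Y = (rng.random(p.shape) < p).astype(float)
    mu_t = items.xi - persons.tau @ Qs.T
    logT = rng.normal(mu_t, 1.0 / items.omega)
    return Y, np.exp(logT)


def simulate_dataset(condition: SimulationCondition, q: QMatrix | None = None,
                     seed: int | None = None, speed_factors: str = "multifactor"):
    """Draw one full dataset plus the generating truth.

    Returns ``(data, persons, items)``.  Sub-streams for persons, items
    and response noise are spawned deterministically from the seed, so
    identical seeds give bit-identical output.  ``speed_factors``
    selects the multifactor or the single-speed-factor generating
    process.
    """
    if q is None:
        q = build_between_item_q(condition.I, condition.K)
    if q.n_items != condition.I or q.n_dims != condition.K:
        raise ValueError("Q-matrix inconsistent with condition")
    seed = condition.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_p, rng_i, rng_n = (np.random.default_rng(s) for s in ss.spawn(3))
    persons = simulate_persons(condition, rng_p, speed_factors)
    items = simulate_items(condition, rng_i)
    q_speed = None
    if speed_factors == "single":
        q_speed = QMatrix(np.ones((condition.I, 1), dtype=np.int8))
    Y, T = simulate_responses(persons, items, q, rng_n, q_speed=q_speed)
    data = JointDataset(Y, T, q)
    return data, persons, items


_PISA_ITEMS = [
    ("CM015Q02D", 0), ("CM015Q03D", 0),
    ("CM020Q01", 1), ("CM020Q02", 1), ("CM020Q03", 1), ("CM020Q04", 1),
    ("CM038Q03T", 2), ("CM038Q05", 2), ("CM038Q06", 2),
]


def pisa_q_fixture() -> QMatrix:
    """The 9-item, 3-dimension Q-matrix of the PISA 2012 released
    computer-based mathematics items (change & relationships, space &
    shape, uncertainty & data)."""
    entries = np.zeros((9, 3), dtype=np.int8)
    for row, (_, k) in enumerate(_PISA_ITEMS):
        entries[row, k] = 1
    return QMatrix(
        entries,
        item_ids=[name for name, _ in _PISA_ITEMS],
        dim_ids=["theta1", "theta2", "theta3"],
    )
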
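"""Model quantities for the joint accuracy/response-time model.

The joint model couples a multidimensional Rasch (MR) model for binary
response accuracy,

    logit P(Y_ni = 1) = sum_k theta_nk q_ik + d_i,

with a multifactor lognormal model (MLRT) for response times,

    log T_ni ~ Normal(xi_i - tautilde_ni, omega_i^-2),
    tautilde_ni = sum_k tau_nk q_ik,

where the binary Q-matrix maps each item to the ability dimension it
measures (between-item multidimensionality: exactly one 1 per row).
Person parameters (theta, tau) follow a multivariate normal with mean
fixed at zero for identification; item parameters (d, xi) follow a
bivariate normal.  With K = 1 the MLRT collapses to the classical
single-factor lognormal response-time model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QMatrix",
    "PersonParams",
    "ItemParams",
    "PopulationStructure",
    "JointDataset",
    "instantaneous_speed",
    "mr_prob",
    "logrt_logdensity",
    "joint_loglik",
    "log1pexp",
    "bernoulli_logmass",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def log1pexp(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable log(1 + exp(x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x > 0
    out[pos] = x[pos] + np.log1p(np.exp(-x[pos]))
    out[~pos] = np.log1p(np.exp(x[~pos]))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class QMatrix:
    """Item-by-dimension binary loading structure.

    Each row marks the single ability dimension an item measures
    (between-item multidimensionality); each dimension must be measured
    by at least one item.
    """

    entries: np.ndarray
    item_ids: list[str] = field(default=None)  # type: ignore[assignment]
    dim_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        entries = np.asarray(self.entries)
        if entries.ndim != 2:
            raise ValueError("Q-matrix must be two-dimensional")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("Q-matrix entries must be 0/1")
        entries = entries.astype(np.int8)
        I, K = entries.shape
        if I < K or K < 1:
            raise ValueError(f"need I >= K >= 1, got I={I}, K={K}")
        row_sums = entries.sum(axis=1)
        if not (row_sums == 1).all():
            bad = np.flatnonzero(row_sums != 1)
            raise ValueError(
                f"between-item structure requires exactly one 1 per row; "
                f"violated at row(s) {bad.tolist()}"
            )
        if (entries.sum(axis=0) < 1).any():
            raise ValueError("every dimension must be measured by at least one item")
        object.__setattr__(self, "entries", entries)
        if self.item_ids is None:
            object.__setattr__(self, "item_ids", [f"item{i + 1}" for i in range(I)])
        if self.dim_ids is None:
            object.__setattr__(self, "dim_ids", [f"dim{k + 1}" for k in range(K)])
        if len(self.item_ids) != I or len(self.dim_ids) != K:
            raise ValueError("label lengths do not match Q-matrix shape")

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_dims(self) -> int:
        return self.entries.shape[1]

    @property
    def dim_of_item(self) -> np.ndarray:
        """Index of the dimension each item loads on."""
        return self.entries.argmax(axis=1)


@dataclass
class PersonParams:
    """Latent person draws: ability ``theta`` (N x K) and speed factors
    ``tau`` (N x K, or N x 1 under a single-speed-factor structure)."""

    theta: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.tau = np.atleast_2d(np.asarray(self.tau, dtype=float))
        if self.theta.shape[0] != self.tau.shape[0]:
            raise ValueError("theta and tau must cover the same persons")
        if not (np.isfinite(self.theta).all() and np.isfinite(self.tau).all()):
            raise ValueError("person parameters must be finite")


@dataclass
class ItemParams:
    """Item draws: easiness ``d``, time-intensity ``xi``, time-precision ``omega``.

    ``omega`` is the reciprocal residual SD of log T (so the residual
    variance is omega**-2).
    """

    d: np.ndarray
    xi: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        self.xi = np.atleast_1d(np.asarray(self.xi, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if not (self.d.shape == self.xi.shape == self.omega.shape):
            raise ValueError("d, xi, omega must share length")
        if (self.omega <= 0).any():
            raise ValueError("omega must be strictly positive")


def _check_pd(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc
    return m


@dataclass
class PopulationStructure:
    """Hyperparameters: person covariance, item mean and item covariance.

    ``sigma_person`` is ordered (theta_1..theta_K, tau_1..tau_Ks); the
    person-level mean is fixed at zero for identification and is not a
    free field.
    """

    sigma_person: np.ndarray
    mu_item: np.ndarray
    sigma_item: np.ndarray

    def __post_init__(self):
        self.sigma_person = _check_pd(self.sigma_person, "sigma_person")
        self.sigma_item = _check_pd(self.sigma_item, "sigma_item")
        self.mu_item = np.atleast_1d(np.asarray(self.mu_item, dtype=float))
        if self.mu_item.shape[0] != self.sigma_item.shape[0]:
            raise ValueError("mu_item length must match sigma_item dimension")

    @property
    def mu_person(self) -> np.ndarray:
        """Always the zero vector (scale identification)."""
        return np.zeros(self.sigma_person.shape[0])


class JointDataset:
    """Paired binary response and positive response-time matrices.

    Missing cells are held as NaN; ``mask_y`` / ``mask_t`` flag observed
    cells independently (the empirical convention: zero response times
    are dropped while the response itself is kept).
    """

    def __init__(self, Y, T, q: QMatrix, mask_y=None, mask_t=None,
                 person_ids=None):
        Y = np.asarray(Y, dtype=float)
        T = np.asarray(T, dtype=float)
        if Y.shape != T.shape:
            raise ValueError("Y and T must share shape")
        if Y.ndim != 2:
            raise ValueError("Y and T must be two-dimensional")
        if Y.shape[1] != q.n_items:
            raise ValueError(
                f"Y has {Y.shape[1]} item columns but Q-matrix has {q.n_items} rows"
            )
        self.mask_y = (~np.isnan(Y)) if mask_y is None else np.asarray(mask_y, bool)
        self.mask_t = (~np.isnan(T)) if mask_t is None else np.asarray(mask_t, bool)
        if self.mask_y.shape != Y.shape or self.mask_t.shape != Y.shape:
            raise ValueError("masks must share the data shape")
        obs_y = Y[self.mask_y]
        if not np.isin(obs_y, (0.0, 1.0)).all():
            bad = np.argwhere(self.mask_y & ~np.isin(Y, (0.0, 1.0)))
            raise ValueError(f"non-binary response at cell(s) {bad[:5].tolist()}")
        obs_t = T[self.mask_t]
        if (obs_t <= 0).any() or np.isnan(obs_t).any():
            bad = np.argwhere(self.mask_t & ~(T > 0))
            raise ValueError(f"observed times must be > 0; violated at {bad[:5].tolist()}")
        self.Y = np.where(self.mask_y, Y, np.nan)
        self.T = np.where(self.mask_t, T, np.nan)
        self.q = q
        self.person_ids = (
            list(person_ids) if person_ids is not None
            else [f"p{n + 1}" for n in range(Y.shape[0])]
        )
        # log-times with masked cells zero-filled, for vectorized updates
        self.logT = np.where(self.mask_t, np.log(np.where(self.mask_t, T, 1.0)), 0.0)
        self.Y0 = np.where(self.mask_y, Y, 0.0)

    @property
    def n_persons(self) -> int:
        return self.Y.shape[0]

    @property
    def n_items(self) -> int:
        return self.Y.shape[1]


def instantaneous_speed(tau: np.ndarray, q: np.ndarray) -> np.ndarray | float:
    """Speed applied to an item: the Q-weighted sum of speed factors.

    Accepts a single (tau_row, q_row) pair or batched arrays whose last
    axis is the dimension axis.
    """
    tau = np.asarray(tau, dtype=float)
    q = np.asarray(q, dtype=float)
    if tau.shape[-1] != q.shape[-1]:
        raise ValueError("tau and q must agree on the dimension axis")
    out = (tau * q).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def mr_prob(theta: np.ndarray, d, q: np.ndarray) -> np.ndarray | float:
    """Correct-response probability under the multidimensional Rasch model.

    Returns inverse-logit(theta . q + d), strictly inside (0, 1).
    """
    theta = np.asarray(theta, dtype=float)
    q = np.asarray(q, dtype=float)
    if theta.shape[-1] != q.shape[-1]:
        raise ValueError("theta and q must agree on the dimension axis")
    eta = (theta * q).sum(axis=-1) + np.asarray(d, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-eta))
    # keep strictly inside (0, 1) even under saturation
    eps = np.finfo(float).tiny
    out = np.clip(out, eps, 1.0 - 1e-16)
    return float(out) if np.ndim(out) == 0 else out


def logrt_logdensity(log_t, xi, tau_tilde, omega) -> np.ndarray | float:
    """Log-density of log T under Normal(xi - tau_tilde, omega**-2)."""
    omega = np.asarray(omega, dtype=float)
    if (omega <= 0).any():
        raise ValueError("omega must be strictly positive")
    z = omega * (np.asarray(log_t, dtype=float) - (np.asarray(xi, float) - np.asarray(tau_tilde, float)))
    out = np.log(omega) - _LOG_SQRT_2PI - 0.5 * z * z
    return float(out) if np.ndim(out) == 0 else out


def bernoulli_logmass(y, eta) -> np.ndarray:
    """Log mass of Bernoulli(y | inverse-logit(eta)) = y*eta - log(1+exp(eta))."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return y * eta - log1pexp(eta)


def joint_loglik(data: JointDataset, persons: PersonParams, items: ItemParams,
                 q_speed: QMatrix | None = None,
                 return_components: bool = True):
    """Joint log-likelihood of responses and log response times.

    Y_ni and log T_ni are conditionally independent given the person and
    item parameters; missing cells contribute exactly zero.  Returns
    ``(total, components)`` where ``components`` is the N x I matrix of
    per-cell contributions (the Y-term plus the T-term when both are
    observed) for pointwise WAIC/DIC use, or just ``total`` when
    ``return_components`` is False.
    """
    Qa = data.q.entries.astype(float)
    Qs = Qa if q_speed is None else q_speed.entries.astype(float)
    theta, tau = persons.theta, persons.tau
    if theta.shape[1] != Qa.shape[1]:
        raise ValueError("theta columns must match ability Q-matrix dimensions")
    if tau.shape[1] != Qs.shape[1]:
        raise ValueError("tau columns must match speed Q-matrix dimensions")
    eta = theta @ Qa.T + items.d            # N x I logits
    y_terms = np.where(data.mask_y, bernoulli_logmass(data.Y0, eta), 0.0)
    mu_t = items.xi - tau @ Qs.T            # N x I means of log T
    z = items.omega * (data.logT - mu_t)
    t_terms = np.where(
        data.mask_t, np.log(items.omega) - _LOG_SQRT_2PI - 0.5 * z * z, 0.0
    )
    components = y_terms + t_terms
    total = float(components.sum())
    if not (data.mask_y.any() or data.mask_t.any()):
        import warnings

        warnings.warn("all cells missing: log-likelihood is 0", stacklevel=2)
    if return_components:
        return total, components
    return total
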
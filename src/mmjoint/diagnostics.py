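"""Convergence diagnostics, posterior predictive checks and model comparison.

PSRF is the classic Gelman-Rubin potential scale reduction factor
computed from whole chains,

    PSRF = sqrt( ((n-1)/n * W + B/n) / W ),

with W the mean within-chain variance and B the between-chain variance
of the chain means (times n).  Values below 1.2 are taken as converged;
well-mixed runs sit below 1.1.

Posterior predictive model checking uses two realized discrepancies:
the sum of squared Pearson residuals of the binary responses, and the
sum of squared standardized errors of the log response times.  The ppp
value is the posterior predictive probability that a replicated
dataset's discrepancy exceeds the realized one; values near 0.5 mean no
systematic misfit, values near 0 or 1 flag misfit.

DIC and WAIC are computed on per-cell joint log-likelihood components
(the (n, i) cell combines the response term and the log-time term when
both are observed).  WAIC uses the variance-form penalty; DIC plugs in
the posterior means of all parameters, including person parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .core import ItemParams, JointDataset, PersonParams, bernoulli_logmass, mr_prob
from .inference import PosteriorChains

__all__ = [
    "FitReport",
    "psrf",
    "psrf_all",
    "max_psrf",
    "discrepancy_ra",
    "discrepancy_rt",
    "ppp",
    "dic",
    "waic",
    "fit_report",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class FitReport:
    ppp_ra: float | None
    ppp_rt: float
    dic: float
    waic: float
    psrf: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


def psrf(chains) -> float:
    """Gelman-Rubin potential scale reduction factor for one scalar.

    ``chains`` is an (n_chains, n_iterations) array or a list of
    equal-length 1-D sequences.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = arr.shape[1]
    W = arr.var(axis=1, ddof=1).mean()
    B = n * arr.mean(axis=1).var(ddof=1)
    if W == 0:
        return np.nan  # flagged as undefined, not a crash
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def psrf_all(chains: PosteriorChains, include_persons: bool = True) -> dict[str, float]:
    """PSRF for every scalar parameter in the retained draws."""
    out = {}
    for name, arr in chains.scalar_draws(include_persons=False).items():
        out[name] = psrf(arr)
    if include_persons:
        for pname in ("theta", "tau"):
            if pname not in chains.draws:
                continue
            arr = chains.draws[pname]            # C x D x N x K
            C, D = arr.shape[:2]
            n = D
            flat = arr.reshape(C, D, -1)
            W = flat.var(axis=1, ddof=1).mean(axis=0)
            B = n * flat.mean(axis=1).var(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.sqrt(((n - 1) / n * W + B / n) / W)
            N, K = arr.shape[2], arr.shape[3]
            for j, v in enumerate(vals):
                out[f"{pname}[{j // K},{j % K}]"] = float(v)
    return out


def max_psrf(chains: PosteriorChains, include_persons: bool = True) -> float:
    vals = np.array(list(psrf_all(chains, include_persons).values()))
    return float(np.nanmax(vals))


def discrepancy_ra(Y, persons: PersonParams, items: ItemParams, q,
                   mask=None, typeset_variant: bool = False) -> float:
    """Sum of squared Pearson residuals of the binary responses.

    ``typeset_variant=True`` computes the literal squared
    (residual / (P(1-P))) form instead of the standard Pearson
    (residual^2 / (P(1-P))) form.
    """
    Y = np.asarray(Y, dtype=float)
    entries = q.entries if hasattr(q, "entries") else np.asarray(q)
    P = mr_prob(persons.theta[:, None, :], items.d, entries[None, :, :].astype(float))
    if mask is None:
        mask = ~np.isnan(Y)
    res = np.where(mask, Y - P, 0.0)
    pq = P * (1 - P)
    if typeset_variant:
        cells = np.where(mask, (res / pq) ** 2, 0.0)
    else:
        cells = np.where(mask, res * res / pq, 0.0)
    return float(cells.sum())


def discrepancy_rt(logT, xi, tau_tilde, omega, mask=None) -> float:
    """Sum of squared standardized errors of log response times."""
    omega = np.asarray(omega, dtype=float)
    if (omega <= 0).any():
        raise ValueError("omega must be positive")
    logT = np.asarray(logT, dtype=float)
    z = omega * (logT - (np.asarray(xi, float) - np.asarray(tau_tilde, float)))
    if mask is None:
        mask = ~np.isnan(logT)
    return float(np.where(mask, z * z, 0.0).sum())


def _draw_params(chains: PosteriorChains, c: int, d: int):
    has_acc = "theta" in chains.draws
    tau = chains.draws["tau"][c, d]
    theta = chains.draws["theta"][c, d] if has_acc else np.zeros_like(tau)
    persons = PersonParams(theta=theta, tau=tau)
    xi = chains.draws["xi"][c, d]
    dd = chains.draws["d"][c, d] if has_acc else np.zeros_like(xi)
    items = ItemParams(d=dd, xi=xi, omega=chains.draws["omega"][c, d])
    return persons, items


def ppp(data: JointDataset, chains: PosteriorChains, discrepancy: str = "rt",
        n_draws: int = 500, seed: int = 0) -> float:
    """Posterior predictive p-value for one discrepancy measure.

    Every k-th retained draw is used so that ``n_draws`` draws span the
    whole retained sample; for each, the realized discrepancy and the
    discrepancy of a dataset replicated from that draw are compared.
    """
    if discrepancy not in ("ra", "rt"):
        raise ValueError("discrepancy must be 'ra' or 'rt'")
    if discrepancy == "ra" and "theta" not in chains.draws:
        raise ValueError("accuracy discrepancy unavailable for a times-only fit")
    if n_draws < 100:
        warnings.warn("ppp with < 100 draws is unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    C, D = chains.n_chains, chains.n_draws
    total = C * D
    take = np.linspace(0, total - 1, num=min(n_draws, total)).astype(int)
    Qs = chains.q_speed.astype(float)
    Qa = chains.q_ability.astype(float) if chains.q_ability is not None else None
    exceed = 0
    for t in take:
        c, d = divmod(int(t), D)
        persons, items = _draw_params(chains, c, d)
        if discrepancy == "ra":
            P = mr_prob(persons.theta[:, None, :], items.d, Qa[None, :, :])
            res = np.where(data.mask_y, data.Y0 - P, 0.0)
            d_obs = float((res * res / (P * (1 - P))).sum())
            y_rep = (rng.random(P.shape) < P).astype(float)
            res_r = np.where(data.mask_y, y_rep - P, 0.0)
            d_rep = float((res_r * res_r / (P * (1 - P))).sum())
        else:
            mu = items.xi - persons.tau @ Qs.T
            z = items.omega * (data.logT - mu)
            d_obs = float(np.where(data.mask_t, z * z, 0.0).sum())
            z_rep = rng.standard_normal(mu.shape)
            d_rep = float(np.where(data.mask_t, z_rep * z_rep, 0.0).sum())
        exceed += d_rep >= d_obs
    return exceed / len(take)


def _pointwise_loglik(data: JointDataset, chains: PosteriorChains,
                      max_draws: int | None = None):
    """Per-draw, per-observed-cell joint log-likelihood matrix."""
    C, D = chains.n_chains, chains.n_draws
    total = C * D
    take = (np.arange(total) if max_draws is None or max_draws >= total
            else np.linspace(0, total - 1, num=max_draws).astype(int))
    cells = data.mask_y | data.mask_t
    idx = np.flatnonzero(cells.ravel())
    Qs = chains.q_speed.astype(float)
    Qa = chains.q_ability.astype(float) if chains.q_ability is not None else None
    out = np.empty((len(take), len(idx)))
    for row, t in enumerate(take):
        c, d = divmod(int(t), D)
        persons, items = _draw_params(chains, c, d)
        ll = np.zeros(data.Y.shape)
        if Qa is not None:
            eta = persons.theta @ Qa.T + items.d
            ll += np.where(data.mask_y, bernoulli_logmass(data.Y0, eta), 0.0)
        mu = items.xi - persons.tau @ Qs.T
        z = items.omega * (data.logT - mu)
        ll += np.where(data.mask_t,
                       np.log(items.omega) - _LOG_SQRT_2PI - 0.5 * z * z, 0.0)
        out[row] = ll.ravel()[idx]
    if not np.isfinite(out).all():
        bad = np.argwhere(~np.isfinite(out))
        raise FloatingPointError(f"non-finite log-likelihood components at {bad[:5].tolist()}")
    return out


def dic(chains: PosteriorChains, data: JointDataset,
        max_draws: int | None = None) -> float:
    """Deviance information criterion with plug-in at posterior means."""
    ll = _pointwise_loglik(data, chains, max_draws)
    mean_dev = -2.0 * ll.sum(axis=1).mean()
    persons = chains.mean_person_params()
    items = chains.mean_item_params()
    Qs = chains.q_speed.astype(float)
    ll_hat = 0.0
    if chains.q_ability is not None:
        eta = persons.theta @ chains.q_ability.astype(float).T + items.d
        ll_hat += float(np.where(data.mask_y, bernoulli_logmass(data.Y0, eta), 0.0).sum())
    mu = items.xi - persons.tau @ Qs.T
    z = items.omega * (data.logT - mu)
    ll_hat += float(np.where(data.mask_t,
                             np.log(items.omega) - _LOG_SQRT_2PI - 0.5 * z * z, 0.0).sum())
    dev_hat = -2.0 * ll_hat
    p_dic = mean_dev - dev_hat
    return dev_hat + 2.0 * p_dic


def waic(chains: PosteriorChains, data: JointDataset,
         max_draws: int | None = None) -> float:
    """Widely applicable information criterion (variance-form penalty)."""
    ll = _pointwise_loglik(data, chains, max_draws)
    S = ll.shape[0]
    m = ll.max(axis=0)
    lppd = float((m + np.log(np.exp(ll - m).mean(axis=0))).sum())
    p_waic = float(ll.var(axis=0, ddof=1).sum()) if S > 1 else 0.0
    return -2.0 * (lppd - p_waic)


def fit_report(data: JointDataset, chains: PosteriorChains,
               n_ppp_draws: int = 500, seed: int = 0,
               max_ic_draws: int | None = 2000,
               include_person_psrf: bool = True) -> FitReport:
    """Bundle ppp values, DIC, WAIC and per-parameter PSRF."""
    has_acc = "theta" in chains.draws
    return FitReport(
        ppp_ra=ppp(data, chains, "ra", n_ppp_draws, seed) if has_acc else None,
        ppp_rt=ppp(data, chains, "rt", n_ppp_draws, seed + 1),
        dic=dic(chains, data, max_ic_draws),
        waic=waic(chains, data, max_ic_draws),
        psrf=psrf_all(chains, include_persons=include_person_psrf),
    )
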
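"""Sampler correctness: conditionals, determinism, structure, calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from mmjoint.core import ItemParams, JointDataset, PersonParams, QMatrix
from mmjoint.inference import (
    JointModel,
    PosteriorChains,
    PriorSpec,
    SamplerConfig,
    posterior_summary,
    run_mcmc,
)
from mmjoint.simulate import (
    SimulationCondition,
    build_between_item_q,
    simulate_dataset,
    simulate_responses,
)


class TestConfigValidation:
    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=100, n_burnin=100)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            SamplerConfig(model_variant="3pl")

    def test_single_chain_warns(self):
        with pytest.warns(UserWarning, match="PSRF"):
            SamplerConfig(n_chains=1)

    def test_draw_count(self):
        cfg = SamplerConfig(n_iterations=800, n_burnin=400, thinning=2)
        assert cfg.n_draws == 200

    def test_prior_df_below_dimension(self):
        with pytest.raises(ValueError, match="df"):
            PriorSpec(person_df=3).resolve(person_dim=6, item_dim=2)

    def test_hyper_mu_spread_readings(self):
        assert PriorSpec(hyperprior_scale_is="variance").hyper_mu_var == 2.0
        assert PriorSpec(hyperprior_scale_is="precision").hyper_mu_var == 0.5

    def test_sklearn_param_plumbing(self):
        m = JointModel(n_iterations=500)
        params = m.get_params()
        assert params["n_iterations"] == 500
        m.set_params(seed=9)
        assert m.seed == 9
        with pytest.raises(ValueError):
            m.set_params(bogus=1)


class TestDeterminism:
    def test_same_seed_identical_chains(self):
        cond = SimulationCondition(N=25, I=6, K=2, seed=3)
        data, *_ = simulate_dataset(cond)
        cfg = SamplerConfig(n_iterations=150, n_burnin=50, seed=11)
        c1 = run_mcmc(data, cfg)
        c2 = run_mcmc(data, cfg)
        for k in c1.draws:
            np.testing.assert_array_equal(c1.draws[k], c2.draws[k])

    def test_different_seed_differs(self):
        cond = SimulationCondition(N=25, I=6, K=2, seed=3)
        data, *_ = simulate_dataset(cond)
        c1 = run_mcmc(data, SamplerConfig(n_iterations=150, n_burnin=50, seed=1))
        c2 = run_mcmc(data, SamplerConfig(n_iterations=150, n_burnin=50, seed=2))
        assert not np.array_equal(c1.draws["xi"], c2.draws["xi"])


class TestPosteriorSummary:
    def _chains_from_scalar(self, arr):
        arr = np.asarray(arr, dtype=float)[:, :, None]
        return PosteriorChains(draws={"xi": arr}, variant="slrt", q_ability=None,
                               q_speed=np.ones((1, 1), dtype=np.int8),
                               config={}, seeds=[0])

    def test_constant_chain(self):
        ch = self._chains_from_scalar([[3.5, 3.5], [3.5, 3.5]])
        s = posterior_summary(ch)
        assert s.loc["xi[0]", "mean"] == 3.5
        assert s.loc["xi[0]", "sd"] == 0.0

    def test_two_chain_mean(self):
        ch = self._chains_from_scalar([[1.0, 3.0], [2.0, 2.0]])
        assert posterior_summary(ch).loc["xi[0]", "mean"] == pytest.approx(2.0)

    def test_chain_order_invariance(self):
        a = self._chains_from_scalar([[1.0, 3.0], [2.0, 2.5]])
        b = self._chains_from_scalar([[2.0, 2.5], [1.0, 3.0]])
        assert posterior_summary(a).loc["xi[0]", "mean"] == \
            posterior_summary(b).loc["xi[0]", "mean"]


class TestConjugateSubcases:
    def test_xi_conditional_matches_closed_form(self):
        """With every other block held fixed, the time-intensity draws are
        iid from the known normal posterior."""
        cond = SimulationCondition(N=50, I=4, K=2, seed=5)
        data, persons, items = simulate_dataset(cond)
        sigma_item = np.diag([1.0, 100.0])       # flat-ish prior on xi
        mu_item = np.array([0.0, 4.0])
        fixed = dict(theta=persons.theta, tau=persons.tau, d=items.d,
                     omega=items.omega, sigma_person=np.eye(4),
                     mu_item=mu_item, sigma_item=sigma_item)
        m = JointModel(n_iterations=900, n_burnin=100, seed=17, fixed=fixed).fit(data)
        draws = m.chains_.pooled("xi")           # (2*800, I)
        tau_tilde = persons.tau @ data.q.entries.astype(float).T
        for i in range(4):
            obs = np.log(data.T[:, i]) + tau_tilde[:, i]
            prec = 1 / 100.0 + items.omega[i] ** 2 * len(obs)
            mean = (4.0 / 100.0 + items.omega[i] ** 2 * obs.sum()) / prec
            sd = 1 / np.sqrt(prec)
            se = sd / np.sqrt(draws.shape[0])    # iid given fixed rest
            assert draws[:, i].mean() == pytest.approx(mean, abs=3 * se + 1e-6)
            assert draws[:, i].std() == pytest.approx(sd, rel=0.15)

    def test_fixed_blocks_stay_fixed(self):
        cond = SimulationCondition(N=20, I=6, K=2, seed=5)
        data, persons, items = simulate_dataset(cond)
        fixed = dict(omega=items.omega, sigma_person=np.eye(4))
        m = JointModel(n_iterations=120, n_burnin=20, seed=1, fixed=fixed).fit(data)
        assert (m.chains_.draws["omega"] == items.omega).all()
        assert (m.chains_.draws["sigma_person"] == np.eye(4)).all()


class TestVariants:
    def test_msj_person_dimension_is_k_plus_one(self):
        cond = SimulationCondition(N=40, I=6, K=3, seed=2)
        data, *_ = simulate_dataset(cond)
        m = JointModel(variant="msj", n_iterations=200, n_burnin=100, seed=4).fit(data)
        assert m.chains_.posterior_mean("sigma_person").shape == (4, 4)
        assert m.chains_.posterior_mean("tau").shape == (40, 1)
        assert m.chains_.q_speed.sum() == 6      # all-ones column

    def test_msj_equals_mmj_when_k_is_one(self):
        """With one dimension the all-ones speed column IS the Q-matrix, so
        the two variants are the same model and the same seeded sampler."""
        cond = SimulationCondition(N=30, I=4, K=1, seed=6)
        data, *_ = simulate_dataset(cond)
        kw = dict(n_iterations=300, n_burnin=100, seed=9)
        mmj = JointModel(variant="mmj", **kw).fit(data)
        msj = JointModel(variant="msj", **kw).fit(data)
        for k in mmj.chains_.draws:
            np.testing.assert_array_equal(mmj.chains_.draws[k], msj.chains_.draws[k])

    def test_fit_msj_wrapper(self):
        cond = SimulationCondition(N=30, I=6, K=2, seed=2)
        data, *_ = simulate_dataset(cond)
        from mmjoint.inference import fit_msj

        ch = fit_msj(data, SamplerConfig(n_iterations=200, n_burnin=100, seed=4))
        assert ch.variant == "msj"
        assert ch.posterior_mean("sigma_person").shape == (3, 3)

    def test_slrt_ignores_responses(self):
        cond = SimulationCondition(N=40, I=6, K=2, seed=2)
        data, *_ = simulate_dataset(cond)
        m = JointModel(variant="slrt", n_iterations=200, n_burnin=100, seed=4).fit(data)
        assert "theta" not in m.chains_.draws
        assert "d" not in m.chains_.draws
        assert m.chains_.posterior_mean("sigma_person").shape == (1, 1)


class TestChainHealth:
    def test_acceptance_rates_in_band(self, fitted_small):
        _, model, *_ = fitted_small
        for rate in model.chains_.acceptance.values():
            assert 0.1 < rate < 0.7

    def test_sigma_person_draws_positive_definite(self, fitted_small):
        _, model, *_ = fitted_small
        for draw in model.chains_.pooled("sigma_person"):
            np.linalg.cholesky(draw)             # raises if not PD

    def test_omega_draws_positive(self, fitted_small):
        _, model, *_ = fitted_small
        assert (model.chains_.pooled("omega") > 0).all()

    def test_population_attribute_valid(self, fitted_small):
        _, model, *_ = fitted_small
        assert model.population_.sigma_person.shape == (6, 6)
        assert np.all(model.population_.mu_person == 0)


class TestPriorSelfConsistency:
    def test_simulation_based_calibration_rank_uniformity(self):
        """Data simulated from prior draws, then fitted: the rank of the
        true hyperparameter among thinned posterior draws must be uniform
        (a miscoded conditional would skew it)."""
        q = build_between_item_q(6, 2)
        Qf = q.entries.astype(float)
        n_sim, n_rank = 36, 40
        ranks_mu, ranks_om = [], []
        root = np.random.SeedSequence(20240)
        for child in root.spawn(n_sim):
            rng = np.random.default_rng(child)
            sigma_p = sps.invwishart.rvs(df=4, scale=np.eye(4), random_state=rng)
            pers = rng.multivariate_normal(np.zeros(4), sigma_p, size=40, method="cholesky")
            persons = PersonParams(theta=pers[:, :2], tau=pers[:, 2:])
            mu_item = np.array([rng.normal(0, np.sqrt(2)), rng.normal(4.3, np.sqrt(2))])
            sigma_i = sps.invwishart.rvs(df=2, scale=np.eye(2), random_state=rng)
            dxi = rng.multivariate_normal(mu_item, sigma_i, size=6, method="cholesky")
            omega = np.sqrt(rng.gamma(1.0, 1.0, size=6))
            items = ItemParams(d=dxi[:, 0], xi=dxi[:, 1], omega=omega)
            Y, T = simulate_responses(persons, items, q, rng)
            data = JointDataset(Y, T, q)
            seed = int(child.generate_state(1)[0] % (2**31))
            m = JointModel(n_iterations=420, n_burnin=220, seed=seed).fit(data)
            mu_draws = m.chains_.pooled("mu_item")[:, 1]
            om_draws = m.chains_.pooled("omega")[:, 0] ** 2
            thin = max(len(mu_draws) // n_rank, 1)
            ranks_mu.append((mu_draws[::thin][:n_rank] < mu_item[1]).sum())
            ranks_om.append((om_draws[::thin][:n_rank] < omega[0] ** 2).sum())
        for ranks in (ranks_mu, ranks_om):
            u = (np.asarray(ranks) + 0.5) / (n_rank + 1)
            assert sps.kstest(u, "uniform").pvalue > 0.005
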
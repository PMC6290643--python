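"""Sampler correctness: initialization recipe, conjugate updates vs closed
forms, the segment sampler vs exhaustive enumeration, prior recovery with no
data, joint-correctness through the simulate/update cycle, and
reproducibility."""

import numpy as np
import pytest
from scipy import stats

import mixlearn as ml
from mixlearn.likelihood import complete_data_loglik, enumerate_profiles, eta_table
from mixlearn.sampler import GibbsSampler, McmcConfig, McmcState, init_chain
from mixlearn.types import (
    DomainError,
    LatentState,
    ObservedData,
    PersonParams,
    QMatrix,
)

from conftest import make_state


def small_data(n=6, seed=0):
    sim = ml.simulate_dataset(ml.SimDesign(n_learners=n, omega=0.2, seed=seed))
    return sim


class TestInitChain:
    def test_deterministic_under_seed(self):
        sim = small_data()
        cfg = McmcConfig(draws=10, burn=1)
        a = init_chain(sim.data, cfg, seed=5)
        b = init_chain(sim.data, cfg, seed=5)
        assert np.array_equal(a.cls, b.cls)
        assert a.lambda0 == b.lambda0 and np.array_equal(a.gamma, b.gamma)

    def test_omega_start_uniform(self):
        sim = small_data()
        cfg = McmcConfig(draws=10, burn=1)
        draws = np.array([init_chain(sim.data, cfg, seed=s).omega
                          for s in range(800)])
        _, p = stats.kstest(draws / 0.2, "uniform")
        assert p > 0.001
        assert draws.max() < 0.2

    def test_sg_constraint_by_construction(self):
        sim = small_data()
        cfg = McmcConfig(draws=10, burn=1)
        for s in range(50):
            st = init_chain(sim.data, cfg, seed=s)
            assert (st.g < 1 - st.s).all()


class TestLatentUpdates:
    def test_segment_sampler_matches_enumeration(self, tiny_k1_data, tiny_k1_params):
        """Gibbs frequencies over (alpha, D) match the exhaustive posterior
        on a single K=1, T=2 learner with fixed parameters."""
        items, persons, structural = tiny_k1_params
        data = tiny_k1_data
        post = {}
        for a1 in (0, 1):
            for a2 in (0, 1):
                for d1 in (0, 1):
                    for d2 in (0, 1):
                        latent = LatentState(alpha=np.array([[[a1], [a2]]]),
                                             d=np.array([[d1, d2]]))
                        post[(a1, a2, d1, d2)] = np.exp(
                            complete_data_loglik(data, latent, items, persons,
                                                 structural))
        z = sum(post.values())
        post = {k: v / z for k, v in post.items()}
        cfg = McmcConfig(draws=10, burn=1)
        smp = GibbsSampler(data, cfg)
        st = make_state(data, items, persons, structural)
        rng = np.random.default_rng(42)
        counts = {}
        n_sweeps = 30_000
        for _ in range(n_sweeps):
            smp.update_latents(st, rng)
            key = (int(st.cls[0, 0]), int(st.cls[0, 1]),
                   int(st.d[0, 0]), int(st.d[0, 1]))
            counts[key] = counts.get(key, 0) + 1
        for key, p in post.items():
            assert counts.get(key, 0) / n_sweeps == pytest.approx(p, abs=0.01)

    def test_disengaged_impossible_across_change(self, tiny_k1_data, tiny_k1_params):
        """When the profile changes between t and t+1, D_t = 1 has zero
        conditional mass (the frozen-transition contract)."""
        items, persons, structural = tiny_k1_params
        cfg = McmcConfig(draws=10, burn=1)
        smp = GibbsSampler(tiny_k1_data, cfg)
        rng = np.random.default_rng(0)
        st = make_state(tiny_k1_data, items, persons, structural,
                        cls=np.array([[0, 1]]))
        for _ in range(300):
            eng, dis = smp.measurement_tables(st)
            lt = smp.transition_table(st)
            smp._update_modes(st, rng, eng, dis, lt)
            if st.cls[0, 0] != st.cls[0, 1]:
                assert st.d[0, 0] == 0

    def test_sweeps_never_violate_invariants(self):
        sim = small_data(n=15, seed=3)
        cfg = McmcConfig(draws=10, burn=1)
        smp = GibbsSampler(sim.data, cfg)
        st = init_chain(sim.data, cfg, seed=1)
        rng = np.random.default_rng(2)
        profiles = enumerate_profiles(4)
        for _ in range(150):
            smp.sweep(st, rng)
            LatentState(alpha=profiles[st.cls], d=st.d).validate()
            assert (st.g < 1 - st.s).all() and (st.a > 0).all()


class TestConjugateUpdates:
    def test_tau_normal_normal_closed_form(self):
        """Two engaged observations: the tau conditional matches the
        hand-computed normal-normal posterior."""
        q = QMatrix(np.array([[1], [1]]))
        data = ObservedData(x=np.array([[1, 1]]),
                            latency=np.array([[np.exp(1.8), np.exp(2.4)]]),
                            item_time=np.array([0, 1]), q=q)
        items = ml.ItemParams(s=np.array([0.1, 0.1]), g=np.array([0.2, 0.2]),
                              gamma=np.array([2.0, 3.0]), a=np.array([2.0, 1.0]))
        persons = PersonParams(theta=np.array([0.0]), tau=np.array([0.0]))
        structural = ml.StructuralParams(
            lambda0=0.0, lambda1=1.0, lambda2=1.0, pi=np.array([0.5, 0.5]),
            omega=0.1, gstar=0.5, mu1=2.0, sigma1_sq=1.0, phi=-0.3,
            sigma_tau_sq=0.5)
        cfg = McmcConfig(draws=10, burn=1)
        smp = GibbsSampler(data, cfg)
        st = make_state(data, items, persons, structural,
                        cls=np.array([[0, 0]]))  # eta = G = 0 on both items
        # closed form: obs_j = gamma_j - log l_j with precision a_j^2
        obs = np.array([2.0 - 1.8, 3.0 - 2.4])
        prec = 1 / 0.5 + 4.0 + 1.0
        mean = (4.0 * obs[0] + 1.0 * obs[1]) / prec
        rng = np.random.default_rng(0)
        draws = []
        for _ in range(4000):
            smp._update_tau(st, rng)
            draws.append(st.tau[0])
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(mean, abs=0.02)
        assert draws.std() == pytest.approx(1 / np.sqrt(prec), rel=0.05)

    def test_tau_prior_when_fully_disengaged(self):
        sim = small_data(n=4, seed=5)
        cfg = McmcConfig(draws=10, burn=1)
        smp = GibbsSampler(sim.data, cfg)
        st = init_chain(sim.data, cfg, seed=0)
        st.d[:] = 1
        st.sigma_tau_sq = 0.6
        rng = np.random.default_rng(1)
        draws = np.array([(smp._update_tau(st, rng), st.tau.copy())[1]
                          for _ in range(2000)])
        assert draws.mean() == pytest.approx(0.0, abs=0.03)
        assert draws.std() == pytest.approx(np.sqrt(0.6), rel=0.05)

    def test_pi_dirichlet_counts(self):
        """Three learners in classes (c1, c1, c2) with K=1: the pi update is
        Dirichlet(1+2, 1+1), checked on moments."""
        q = QMatrix(np.array([[1]]))
        data = ObservedData(x=np.array([[1], [1], [0]]),
                            latency=np.full((3, 1), 5.0),
                            item_time=np.array([0]), q=q)
        cfg = McmcConfig(draws=10, burn=1)
        smp = GibbsSampler(data, cfg)
        st = init_chain(data, cfg, seed=0)
        st.cls = np.array([[0], [0], [1]])
        rng = np.random.default_rng(3)
        draws = []
        for _ in range(4000):
            smp.update_structural_params(st, rng)
            draws.append(st.pi[0])
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(3 / 5, abs=0.02)  # Dir(3,2)

    def test_omega_posterior_no_disengagement(self):
        """With all D = 0 the omega conditional is Beta(1, 1 + NT)."""
        sim = small_data(n=5, seed=6)
        nt = 5 * 4
        cfg = McmcConfig(draws=10, burn=1)
        smp = GibbsSampler(sim.data, cfg)
        st = init_chain(sim.data, cfg, seed=0)
        st.d[:] = 0
        rng = np.random.default_rng(4)
        draws = []
        for _ in range(4000):
            smp.update_structural_params(st, rng)
            st.d[:] = 0
            draws.append(st.omega)
        assert np.mean(draws) == pytest.approx(1 / (nt + 2), abs=0.005)

    def test_gstar_beta_moments(self):
        """g* sweeps on a frozen tiny dataset match the Beta posterior."""
        sim = small_data(n=5, seed=7)
        cfg = McmcConfig(draws=10, burn=1)
        smp = GibbsSampler(sim.data, cfg)
        st = init_chain(sim.data, cfg, seed=0)
        st.d[:] = 0
        st.d[0, :] = 1  # learner 0 disengaged at all four modules
        dis = st.d[:, sim.data.item_time] == 1
        n_corr = sim.data.x[dis].sum()
        n_cell = dis.sum()
        a_post, b_post = 1 + n_corr, 1 + n_cell - n_corr
        d_frozen = st.d.copy()
        rng = np.random.default_rng(5)
        draws = []
        for _ in range(4000):
            smp.update_structural_params(st, rng)
            st.d = d_frozen.copy()
            draws.append(st.gstar)
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(a_post / (a_post + b_post), abs=0.02)
        assert draws.std() == pytest.approx(stats.beta.std(a_post, b_post), rel=0.15)

    def test_gamma_normal_normal_closed_form(self):
        """Time-intensity conditional on a fixed toy item matches the
        normal-normal posterior."""
        q = QMatrix(np.array([[1]]))
        logs = np.array([2.0, 2.5, 3.0])
        data = ObservedData(x=np.ones((3, 1), dtype=int),
                            latency=np.exp(logs)[:, None],
                            item_time=np.array([0]), q=q)
        cfg = McmcConfig(draws=10, burn=1)
        smp = GibbsSampler(data, cfg)
        st = init_chain(data, cfg, seed=0)
        st.d[:] = 0
        st.cls[:] = 0  # eta = 0, so G = 0
        st.tau[:] = 0.0
        st.a[:] = 2.0
        a2 = 4.0
        prec = 1.0 + 3 * a2
        mean = a2 * logs.sum() / prec
        rng = np.random.default_rng(6)
        draws = []
        for _ in range(4000):
            keep = (st.s.copy(), st.g.copy(), st.a.copy())
            smp.update_item_params(st, rng)
            st.s, st.g, st.a = keep  # isolate the gamma step
            st.tau[:] = 0.0
            draws.append(st.gamma[0])
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(mean, abs=0.02)
        assert draws.std() == pytest.approx(1 / np.sqrt(prec), rel=0.06)

    def test_a_sq_gamma_shape_arithmetic(self):
        """The discrimination update shape is prior shape + n/2."""
        sim = small_data(n=8, seed=8)
        # pin the time intensity with a near-degenerate prior so the residual
        # sum is constant and the a^2 draws come from one Gamma distribution
        prior = ml.PriorSpec(gamma_mean=3.0, gamma_sd=1e-6)
        cfg = McmcConfig(draws=10, burn=1, prior=prior)
        smp = GibbsSampler(sim.data, cfg)
        st = init_chain(sim.data, cfg, seed=0)
        st.d[:] = 0
        n_j = (st.d[:, sim.data.item_time] == 0).sum(axis=0)
        assert (n_j == 8).all()
        rng = np.random.default_rng(7)
        draws = []
        for _ in range(6000):
            keep = (st.s.copy(), st.g.copy(), st.tau.copy())
            smp.update_item_params(st, rng)
            st.s, st.g, st.tau = keep
            draws.append(st.a[0] ** 2)
        draws = np.array(draws)
        # shape = prior shape + n/2 = 5 recovered from the moment ratio
        shape_implied = draws.mean() ** 2 / draws.var()
        assert shape_implied == pytest.approx(1 + 8 / 2, rel=0.1)


class TestRunMcmc:
    def test_prior_recovery_zero_data(self):
        """With zero learners every conditional reduces to its prior."""
        q = QMatrix(np.array([[1, 0], [0, 1]]))
        data = ObservedData(x=np.zeros((0, 2)), latency=np.ones((0, 2)),
                            item_time=np.array([0, 1]), q=q)
        s = ml.run_mcmc(data, McmcConfig(draws=3000, burn=0, seed=11))
        assert s.structural["omega"].mean() == pytest.approx(0.5, abs=0.03)
        assert s.structural["omega"].std() == pytest.approx(np.sqrt(1 / 12), abs=0.02)
        assert s.structural["gstar"].mean() == pytest.approx(0.5, abs=0.03)
        assert s.structural["mu1"].mean() == pytest.approx(0.0, abs=0.08)
        assert s.structural["mu1"].std() == pytest.approx(1.0, abs=0.08)
        assert s.structural["sigma_tau_sq"].mean() == pytest.approx(2 / 3, abs=0.1)
        assert np.log(s.structural["lambda2"]).std() == pytest.approx(0.6, abs=0.1)

    def test_joint_correctness_successive_conditional(self):
        """Geweke-style check on K=1, N=5, T=2: alternating data simulation
        and one Gibbs sweep leaves the prior marginals of omega, g*, mu1
        invariant."""
        rng = np.random.default_rng(17)
        q = QMatrix(np.array([[1], [1], [1], [1]]))
        item_time = np.array([0, 0, 1, 1])
        n, t, k = 5, 2, 1
        cfg = McmcConfig(draws=10, burn=1)
        profiles = enumerate_profiles(k)
        bits = 1 << np.arange(k)

        def draw_prior_state():
            while True:
                s_, g_ = rng.random(4), rng.random(4)
                if (g_ < 1 - s_).all():
                    break
            return McmcState(
                cls=np.zeros((n, t), dtype=np.int64),
                d=np.zeros((n, t), dtype=np.int8),
                theta=rng.standard_normal(n), tau=rng.standard_normal(n),
                s=s_, g=g_, gamma=rng.normal(0, 1, 4),
                a=np.sqrt(rng.gamma(1.0, 1.0, 4)),
                lambda0=rng.normal(), lambda1=np.exp(rng.normal(0.5, 1)),
                lambda2=np.exp(rng.normal(-0.5, 0.6)),
                pi=rng.dirichlet(np.ones(2)), omega=rng.beta(1, 1),
                gstar=rng.beta(1, 1), mu1=rng.normal(),
                sigma1_sq=1 / rng.gamma(1.0, 1.0), phi=rng.normal(),
                sigma_tau_sq=1 / rng.gamma(2.5, 1.0))

        def simulate_given(st):
            theta = rng.standard_normal(n)
            tau = rng.normal(0, np.sqrt(st.sigma_tau_sq), n)
            d = (rng.random((n, t)) < st.omega).astype(np.int8)
            cls = np.zeros((n, t), dtype=np.int64)
            cls[:, 0] = rng.choice(2, size=n, p=st.pi)
            cur = profiles[cls[:, 0]]
            z = st.lambda0 + st.lambda1 * theta + st.lambda2 * cur.sum(1)
            p = 1 / (1 + np.exp(-z))
            gains = (rng.random((n, k)) < p[:, None]) & (cur == 0)
            nxt = np.where(gains, 1, cur)
            nxt[d[:, 0] == 1] = cur[d[:, 0] == 1]
            cls[:, 1] = nxt @ bits
            eta = eta_table(q.q)
            ec = eta[cls[:, item_time], np.arange(4)[None, :]]
            dis = d[:, item_time].astype(bool)
            p_corr = np.where(dis, st.gstar,
                              np.where(ec == 1, 1 - st.s[None, :], st.g[None, :]))
            x = (rng.random((n, 4)) < p_corr).astype(np.int8)
            mean = st.gamma[None, :] - (tau[:, None] + st.phi * ec)
            ll = np.where(dis,
                          rng.normal(st.mu1, np.sqrt(st.sigma1_sq), (n, 4)),
                          rng.standard_normal((n, 4)) / st.a[None, :] + mean)
            st.theta, st.tau, st.d, st.cls = theta, tau, d, cls
            return ObservedData(x=x, latency=np.exp(ll), item_time=item_time, q=q)

        st = draw_prior_state()
        oms, gss, mu1s = [], [], []
        for _ in range(2500):
            data = simulate_given(st)
            GibbsSampler(data, cfg).sweep(st, rng)
            oms.append(st.omega)
            gss.append(st.gstar)
            mu1s.append(st.mu1)
        assert np.mean(oms) == pytest.approx(0.5, abs=0.05)
        assert np.std(oms) == pytest.approx(np.sqrt(1 / 12), abs=0.03)
        assert np.mean(gss) == pytest.approx(0.5, abs=0.05)
        assert np.mean(mu1s) == pytest.approx(0.0, abs=0.12)
        assert np.std(mu1s) == pytest.approx(1.0, abs=0.1)

    def test_seed_reproducibility(self):
        sim = small_data(n=10, seed=12)
        cfg = McmcConfig(draws=80, burn=20, seed=33)
        a = ml.run_mcmc(sim.data, cfg)
        b = ml.run_mcmc(sim.data, cfg)
        for k in a.structural:
            assert np.array_equal(a.structural[k], b.structural[k])
        assert np.array_equal(a.alpha_freq, b.alpha_freq)
        assert np.array_equal(a.deviance, b.deviance)


class TestPosteriorSummaries:
    def test_dichotomization_and_ties(self):
        sim = small_data(n=5, seed=13)
        s = ml.run_mcmc(sim.data, McmcConfig(draws=60, burn=20, seed=1))
        s.alpha_freq[:] = 0.7
        s.alpha_freq[0, 0, 0] = 0.3
        s.alpha_freq[0, 0, 1] = 0.5  # exact tie resolves to non-mastery
        s.d_freq[:] = 0.2
        summ = ml.posterior_summaries(s)
        assert summ.alpha_hat[1, 1, 1] == 1
        assert summ.alpha_hat[0, 0, 0] == 0
        assert summ.alpha_hat[0, 0, 1] == 0
        assert (summ.d_hat == 0).all()

    def test_eap_equals_trace_mean(self):
        sim = small_data(n=5, seed=14)
        s = ml.run_mcmc(sim.data, McmcConfig(draws=100, burn=40, seed=2))
        summ = ml.posterior_summaries(s)
        assert summ.structural["omega"][0] == pytest.approx(
            s.structural["omega"][40:].mean())
        assert summ.structural["omega"][1] == pytest.approx(
            s.structural["omega"][40:].std())

    def test_empty_sample_errors(self):
        with pytest.raises(DomainError):
            ml.posterior_summaries([])
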
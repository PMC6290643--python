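"""Metropolis-Hastings-within-Gibbs sampler for the mixture learning model.

One sweep updates, in order: the discrete latent states (profile segments,
then engagement modes), the person parameters (theta by random-walk MH, tau
by its conjugate normal), the item parameters (order-constrained Beta pairs
for slipping/guessing, conjugate normal/Gamma for the RT parameters), and
the structural parameters (Dirichlet/Beta/normal/inverse-gamma conjugate
steps, random-walk MH for the transition coefficients).

Profile segments: runs of consecutive time points tied together by
disengaged modes share one profile, so they are sampled jointly over the
2^K classes — conditioning on the profile before the segment (or the
initial-class simplex), the profile after it, and the responses/response
times at the segment's engaged time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .likelihood import enumerate_profiles, eta_table
from .types import (
    DomainError,
    ItemParams,
    ObservedData,
    PersonParams,
    PriorSpec,
    StructuralParams,
)

_LOG_2PI = float(np.log(2.0 * np.pi))


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -z)


@dataclass
class McmcConfig:
    """Chain settings. Defaults mirror the production recipe of the study
    design (30,000 sweeps, 5,000 burn-in); tests and desk-scale runs pass
    shorter chains."""

    draws: int = 30_000
    burn: int = 5_000
    chains: int = 1
    seed: int | None = None
    theta_scale: float = 0.5
    lambda_scale: float = 0.2
    # inner random-walk refreshes per sweep; several cheap proposals per
    # sweep shorten the autocorrelation of the weakly-identified
    # transition block and of the person abilities coupled to it
    theta_steps: int = 3
    lambda_steps: int = 5
    adapt: bool = True
    adapt_window: int = 50
    mixture: bool = True
    store_person: bool = True
    n_ppc_snapshots: int = 50
    # extra latent+person passes per sweep; the discrete states and person
    # traits mix slower than the conjugate blocks, so refreshing them twice
    # per stored draw shortens autocorrelation times at modest cost
    extra_latent_sweeps: int = 1
    prior: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if not 0 <= self.burn < self.draws:
            raise DomainError("burn-in must be shorter than the chain")
        if self.theta_scale <= 0 or self.lambda_scale <= 0:
            raise DomainError("proposal scales must be positive")

    @classmethod
    def production(cls, **kw) -> "McmcConfig":
        """30,000 sweeps with a 5,000-sweep burn-in."""
        kw.setdefault("draws", 30_000)
        kw.setdefault("burn", 5_000)
        return cls(**kw)

    @classmethod
    def extended(cls, **kw) -> "McmcConfig":
        """45,000 sweeps discarding the first 20,000 (long-burn preset)."""
        kw.setdefault("draws", 45_000)
        kw.setdefault("burn", 20_000)
        return cls(**kw)


@dataclass
class McmcState:
    """One complete configuration of parameters and latent states."""

    cls: np.ndarray  # (N, T) integer profile classes
    d: np.ndarray  # (N, T) engagement modes
    theta: np.ndarray
    tau: np.ndarray
    s: np.ndarray
    g: np.ndarray
    gamma: np.ndarray
    a: np.ndarray
    lambda0: float
    lambda1: float
    lambda2: float
    pi: np.ndarray
    omega: float
    gstar: float
    mu1: float
    sigma1_sq: float
    phi: float
    sigma_tau_sq: float

    def alpha(self) -> np.ndarray:
        k = int(np.log2(self.pi.shape[0]))
        return enumerate_profiles(k)[self.cls]


STRUCTURAL_FIELDS = ("lambda0", "lambda1", "lambda2", "omega", "gstar",
                     "mu1", "sigma1_sq", "phi", "sigma_tau_sq")


@dataclass
class McmcSamples:
    """Stored draws of one chain (full length; burn-in retained so that
    convergence diagnostics can choose their own split)."""

    structural: dict  # name -> (draws,) arrays
    pi: np.ndarray  # (draws, C)
    item: dict  # name -> (draws, J)
    person: dict  # name -> (draws, N) (may be empty)
    deviance: np.ndarray  # (draws,)
    alpha_freq: np.ndarray  # (N, T, K) post-burn-in inclusion frequencies
    d_freq: np.ndarray  # (N, T)
    snapshots: list  # thinned post-burn-in state snapshots for PPC
    burn: int
    seed: int | None
    acceptance: dict
    config: McmcConfig

    @property
    def draws(self) -> int:
        return self.deviance.shape[0]

    def scalar_traces(self, include_person: bool = True) -> dict:
        """Flat name -> full-length trace mapping over every parameter."""
        out = {k: v for k, v in self.structural.items()}
        for c in range(self.pi.shape[1]):
            out[f"pi[{c}]"] = self.pi[:, c]
        for name, arr in self.item.items():
            for j in range(arr.shape[1]):
                out[f"{name}[{j}]"] = arr[:, j]
        if include_person:
            for name, arr in self.person.items():
                for i in range(arr.shape[1]):
                    out[f"{name}[{i}]"] = arr[:, i]
        return out


def init_chain(data: ObservedData, config: McmcConfig, seed=None) -> McmcState:
    """Draw initial values from the dispersed starting recipe.

    Fixed parameters: lambda0 ~ N(0,1), lambda1, lambda2 ~ U(0,1),
    pi ~ Dirichlet(1), phi ~ U(0,1), omega ~ U(0, 0.2), g* ~ U(0, 0.5),
    s_j, g_j ~ U(0, 0.3), mu1 ~ N(2,1), sigma1 ~ U(0,1),
    gamma_j ~ N(3.45, 0.5^2), a_j ~ U(2,4), sigma_tau^2 ~ Inv-Gamma(1,1);
    latent states are then simulated forward given these.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, J, K = data.n_learners, data.n_items, data.n_skills
    T = data.n_times
    C = 2 ** K
    lam0 = rng.normal(0.0, 1.0)
    lam1 = max(rng.uniform(0.0, 1.0), 1e-6)
    lam2 = max(rng.uniform(0.0, 1.0), 1e-6)
    pi = rng.dirichlet(np.ones(C))
    phi = rng.uniform(0.0, 1.0)
    omega = rng.uniform(0.0, 0.2) if config.mixture else 0.0
    gstar = min(max(rng.uniform(0.0, 0.5), 1e-6), 1 - 1e-6)
    s = rng.uniform(0.0, 0.3, size=J)
    g = rng.uniform(0.0, 0.3, size=J)
    mu1 = rng.normal(2.0, 1.0)
    sigma1 = max(rng.uniform(0.0, 1.0), 1e-3)
    gamma = rng.normal(3.45, 0.5, size=J)
    a = rng.uniform(2.0, 4.0, size=J)
    sigma_tau_sq = 1.0 / rng.gamma(1.0, 1.0)

    theta = rng.standard_normal(n)
    tau = rng.normal(0.0, np.sqrt(sigma_tau_sq), size=n)
    d = (rng.random((n, T)) < omega).astype(np.int8)
    cls = np.zeros((n, T), dtype=np.int64)
    profiles = enumerate_profiles(K)
    m_of = profiles.sum(axis=1)
    cls[:, 0] = rng.choice(C, size=n, p=pi)
    bits = 1 << np.arange(K)
    for t in range(T - 1):
        cur = profiles[cls[:, t]]
        z = lam0 + lam1 * theta + lam2 * m_of[cls[:, t]]
        p = 1.0 / (1.0 + np.exp(-z))
        gains = (rng.random((n, K)) < p[:, None]) & (cur == 0)
        nxt = np.where(gains, 1, cur)
        frozen = d[:, t] == 1
        nxt[frozen] = cur[frozen]
        cls[:, t + 1] = nxt @ bits
    return McmcState(cls=cls, d=d, theta=theta, tau=tau, s=s, g=g, gamma=gamma,
                     a=a, lambda0=lam0, lambda1=lam1, lambda2=lam2, pi=pi,
                     omega=omega, gstar=gstar, mu1=mu1, sigma1_sq=sigma1 ** 2,
                     phi=phi, sigma_tau_sq=sigma_tau_sq)


class GibbsSampler:
    """Holds the data in sampler-friendly layout and performs sweeps.

    Exposed so tests can drive individual update blocks against oracles;
    :func:`run_mcmc` is the high-level entry point.
    """

    def __init__(self, data: ObservedData, config: McmcConfig):
        self.data = data
        self.config = config
        self.prior = config.prior
        self.n = data.n_learners
        self.T = data.n_times
        self.K = data.n_skills
        self.J = data.n_items
        self.C = 2 ** self.K
        self.profiles = enumerate_profiles(self.K)  # (C, K)
        self.m_of = self.profiles.sum(axis=1).astype(np.int64)  # (C,)
        self.eta = eta_table(data.q.q)  # (C, J)
        self.t_of = data.item_time  # (J,)
        self.jt = [data.items_at(t) for t in range(self.T)]
        self.x = data.x.astype(np.float64)
        self.log_l = np.log(data.latency)
        # per-module sufficient statistics for the disengaged component
        self.jt_sizes = np.array([len(j) for j in self.jt])
        self.sx = np.stack([self.x[:, j].sum(axis=1) for j in self.jt], axis=1)
        self.sl = np.stack([self.log_l[:, j].sum(axis=1) for j in self.jt], axis=1)
        self.sl2 = np.stack([(self.log_l[:, j] ** 2).sum(axis=1) for j in self.jt], axis=1)
        # reachability and count masks over (source class, target class)
        m = self.m_of
        reach = (self.profiles[:, None, :] <= self.profiles[None, :, :]).all(axis=2)
        self.reach = reach
        self.n_new = (m[None, :] - m[:, None]).astype(np.float64)  # m_c' - m_c
        self.n_rem = (self.K - m[None, :]) * np.ones((self.C, 1))
        self.item_index = np.arange(self.J)
        # MH bookkeeping
        self.theta_scale = config.theta_scale
        self.lambda_scale = config.lambda_scale
        self._acc = {"theta": 0.0, "theta_n": 0.0, "lambda": 0.0, "lambda_n": 0.0}
        self._win = {"theta": 0.0, "theta_n": 0.0, "lambda": 0.0, "lambda_n": 0.0}

    # ---------------- per-sweep likelihood tables ----------------

    def measurement_tables(self, st: McmcState):
        """(engaged measurement lp (N,T,C), disengaged measurement lp (N,T)).

        Engaged entries combine the DINA response log-pmf and the engaged
        log-normal RT log-pdf for every candidate profile class; disengaged
        entries are class-free.
        """
        s, g, gamma, a = st.s, st.g, st.gamma, st.a
        eta = self.eta.astype(np.float64)
        logp_c = eta * np.log1p(-s)[None, :] + (1 - eta) * np.log(g)[None, :]
        logp_w = eta * np.log(s)[None, :] + (1 - eta) * np.log1p(-g)[None, :]
        a2 = a ** 2
        r = self.log_l + st.tau[:, None] - gamma[None, :]  # (N, J)
        a2r2 = a2[None, :] * r ** 2
        a2r = a2[None, :] * r
        eng = np.empty((self.n, self.T, self.C))
        for t, j in enumerate(self.jt):
            resp = self.x[:, j] @ logp_c[:, j].T + (1 - self.x[:, j]) @ logp_w[:, j].T
            g_t = eta[:, j]  # (C, Jt)
            const = (np.log(a[j]).sum() - 0.5 * len(j) * _LOG_2PI
                     - self.log_l[:, j].sum(axis=1))
            quad = (a2r2[:, j].sum(axis=1)[:, None]
                    + 2.0 * st.phi * (a2r[:, j] @ g_t.T)
                    + st.phi ** 2 * (a2[j][None, :] * g_t).sum(axis=1)[None, :])
            eng[:, t, :] = resp + const[:, None] - 0.5 * quad
        n_t = self.jt_sizes[None, :]
        dis = (self.sx * np.log(st.gstar) + (n_t - self.sx) * np.log1p(-st.gstar)
               - 0.5 * (self.sl2 - 2 * st.mu1 * self.sl + n_t * st.mu1 ** 2) / st.sigma1_sq
               - 0.5 * n_t * (_LOG_2PI + np.log(st.sigma1_sq)) - self.sl)
        return eng, dis

    def transition_table(self, st: McmcState) -> np.ndarray:
        """Log transition probabilities (N, C, C) for engaged steps.

        Unreachable targets (losing a mastered skill) carry -inf; the
        per-skill acquisition probability depends only on the learner and
        the source class's mastery count.
        """
        z = (st.lambda0 + st.lambda1 * st.theta[:, None]
             + st.lambda2 * np.arange(self.K + 1)[None, :])  # (N, K+1)
        lp = _log_sigmoid(z)
        l1p = _log_sigmoid(-z)
        lp_src = lp[:, self.m_of]  # (N, C)
        l1p_src = l1p[:, self.m_of]
        lt = (self.n_new[None, :, :] * lp_src[:, :, None]
              + self.n_rem[None, :, :] * l1p_src[:, :, None])
        lt[:, ~self.reach] = -np.inf
        return lt

    def deviance(self, st: McmcState, tables=None) -> float:
        """-2 x (response + RT) log-likelihood at the current latent states."""
        eng, dis = tables if tables is not None else self.measurement_tables(st)
        ii = np.arange(self.n)[:, None]
        tt = np.arange(self.T)[None, :]
        val = np.where(st.d == 1, dis, eng[ii, tt, st.cls])
        return float(-2.0 * val.sum())

    # ---------------- update blocks ----------------

    def update_latents(self, st: McmcState, rng, tables=None) -> None:
        eng, dis = tables if tables is not None else self.measurement_tables(st)
        lt = self.transition_table(st)
        self._update_alpha_segments(st, rng, eng, lt)
        if self.config.mixture:
            self._update_modes(st, rng, eng, dis, lt)

    def _update_alpha_segments(self, st, rng, eng, lt) -> None:
        n, T, C = self.n, self.T, self.C
        if n == 0:
            return
        with np.errstate(divide="ignore"):
            log_pi = np.log(st.pi)
        d, cls = st.d, st.cls
        brk = np.ones((n, T), dtype=bool)
        brk[:, 1:] = d[:, :-1] == 0
        seg = np.cumsum(brk, axis=1) - 1  # (N, T) segment id of each time
        nseg = seg[:, -1] + 1
        maxseg = int(nseg.max())
        seg_start = np.zeros((n, maxseg), dtype=np.int64)
        seg_end = np.zeros((n, maxseg), dtype=np.int64)
        for t in range(T):
            sid = seg[:, t]
            seg_end[np.arange(n), sid] = t
            started = brk[:, t]
            seg_start[np.arange(n)[started], sid[started]] = t
        rows_all = np.arange(n)
        for sidx in range(maxseg):
            active = np.flatnonzero(sidx < nseg)
            if active.size == 0:
                continue
            t0 = seg_start[active, sidx]
            t1 = seg_end[active, sidx]
            lp = np.zeros((active.size, C))
            first = t0 == 0
            lp[first] += log_pi[None, :]
            prev_rows = active[~first]
            if prev_rows.size:
                prev_cls = cls[prev_rows, t0[~first] - 1]
                lp[~first] += lt[prev_rows, prev_cls, :]
            has_out = t1 < T - 1
            out_rows = active[has_out]
            if out_rows.size:
                nxt_cls = cls[out_rows, t1[has_out] + 1]
                lp[has_out] += lt[out_rows[:, None], np.arange(C)[None, :], nxt_cls[:, None]]
            eng_end = d[active, t1] == 0
            e_rows = active[eng_end]
            if e_rows.size:
                lp[eng_end] += eng[e_rows, t1[eng_end], :]
            gumb = rng.gumbel(size=lp.shape)
            new_cls = np.argmax(np.where(np.isneginf(lp), -np.inf, lp) + gumb, axis=1)
            for off in range(T):
                fill = t0 + off <= t1
                if not fill.any():
                    break
                cls[active[fill], t0[fill] + off] = new_cls[fill]

    def _update_modes(self, st, rng, eng, dis, lt) -> None:
        n, T = self.n, self.T
        if n == 0:
            return
        cls, d = st.cls, st.d
        log_om = np.log(st.omega) if st.omega > 0 else -np.inf
        log_1mom = np.log1p(-st.omega) if st.omega < 1 else -np.inf
        ii = np.arange(n)[:, None]
        tt = np.arange(T)[None, :]
        cur = cls
        lw1 = log_om + dis
        lw0 = log_1mom + eng[ii, tt, cur]
        if T > 1:
            same = cls[:, 1:] == cls[:, :-1]
            lw1[:, :-1] += np.where(same, 0.0, -np.inf)
            lw0[:, :-1] += lt[ii[:, : T - 1], cls[:, :-1], cls[:, 1:]]
        # two-point conditional via a log-sum-exp-stable Bernoulli draw
        p1 = 1.0 / (1.0 + np.exp(np.clip(lw0 - lw1, -700, 700)))
        p1 = np.where(np.isneginf(lw1), 0.0, p1)
        p1 = np.where(np.isneginf(lw0) & ~np.isneginf(lw1), 1.0, p1)
        st.d = (rng.random((n, T)) < p1).astype(np.int8)

    def update_person_params(self, st: McmcState, rng) -> None:
        self._update_theta(st, rng)
        self._update_tau(st, rng)

    def _transition_suffstats(self, st):
        """Mastery counts (source, target) and engagement mask per step."""
        m_t = self.m_of[st.cls[:, : self.T - 1]]
        m_t1 = self.m_of[st.cls[:, 1:]]
        w = (st.d[:, : self.T - 1] == 0).astype(np.float64)
        return m_t.astype(np.float64), m_t1.astype(np.float64), w

    def _theta_loglik(self, theta, st, m_t, m_t1, w):
        z = st.lambda0 + st.lambda1 * theta[:, None] + st.lambda2 * m_t
        lp = (m_t1 - m_t) * _log_sigmoid(z) + (self.K - m_t1) * _log_sigmoid(-z)
        return (lp * w).sum(axis=1)

    def _update_theta(self, st, rng) -> None:
        if self.n == 0 or self.T < 2:
            if self.n:
                st.theta = rng.standard_normal(self.n)
            return
        m_t, m_t1, w = self._transition_suffstats(st)
        cur = self._theta_loglik(st.theta, st, m_t, m_t1, w)
        for _ in range(self.config.theta_steps):
            prop = st.theta + self.theta_scale * rng.standard_normal(self.n)
            new = self._theta_loglik(prop, st, m_t, m_t1, w)
            log_r = new - cur - 0.5 * (prop ** 2 - st.theta ** 2)
            acc = np.log(rng.random(self.n)) < log_r
            st.theta = np.where(acc, prop, st.theta)
            cur = np.where(acc, new, cur)
            self._acc["theta"] += acc.sum()
            self._acc["theta_n"] += self.n
            self._win["theta"] += acc.sum()
            self._win["theta_n"] += self.n

    def _update_tau(self, st, rng) -> None:
        if self.n == 0:
            return
        engaged = (st.d[:, self.t_of] == 0).astype(np.float64)  # (N, J)
        a2 = st.a ** 2
        g_cells = self.eta[st.cls[:, self.t_of], self.item_index[None, :]]
        y = st.gamma[None, :] - st.phi * g_cells - self.log_l
        prec = 1.0 / st.sigma_tau_sq + engaged @ a2
        mean = (engaged * y) @ a2 / prec
        st.tau = mean + rng.standard_normal(self.n) / np.sqrt(prec)

    def update_item_params(self, st: McmcState, rng) -> None:
        pr = self.prior
        engaged = (st.d[:, self.t_of] == 0).astype(np.float64)
        g_cells = self.eta[st.cls[:, self.t_of], self.item_index[None, :]].astype(np.float64)
        x = self.x
        n11 = (engaged * g_cells * x).sum(axis=0)
        n10 = (engaged * g_cells * (1 - x)).sum(axis=0)
        n01 = (engaged * (1 - g_cells) * x).sum(axis=0)
        n00 = (engaged * (1 - g_cells) * (1 - x)).sum(axis=0)
        # slipping truncated to (0, 1 - g), then guessing to (0, 1 - s)
        a_s, b_s = pr.a_s + n10, pr.b_s + n11
        hi = stats.beta.cdf(1.0 - st.g, a_s, b_s)
        u = rng.random(self.J)
        s = stats.beta.ppf(np.maximum(u * hi, 1e-300), a_s, b_s)
        s = np.clip(s, 1e-9, 1.0 - 1e-9)
        a_g, b_g = pr.a_g + n01, pr.b_g + n00
        hi_g = stats.beta.cdf(1.0 - s, a_g, b_g)
        u2 = rng.random(self.J)
        g = stats.beta.ppf(np.maximum(u2 * hi_g, 1e-300), a_g, b_g)
        g = np.clip(g, 1e-9, None)
        g = np.minimum(g, 1.0 - s - 1e-9)
        st.s, st.g = s, g
        # time intensity: conjugate normal with per-item precision n_j a_j^2
        a2 = st.a ** 2
        obs = self.log_l + st.tau[:, None] + st.phi * g_cells
        n_j = engaged.sum(axis=0)
        prec = 1.0 / pr.gamma_sd ** 2 + n_j * a2
        mean = (pr.gamma_mean / pr.gamma_sd ** 2 + a2 * (engaged * obs).sum(axis=0)) / prec
        st.gamma = mean + rng.standard_normal(self.J) / np.sqrt(prec)
        # squared discrimination: conjugate Gamma on the log-RT precision
        resid = self.log_l - st.gamma[None, :] + st.tau[:, None] + st.phi * g_cells
        ssr = (engaged * resid ** 2).sum(axis=0)
        a_sq = rng.gamma(pr.a_sq_shape + 0.5 * n_j, 1.0 / (pr.a_sq_rate + 0.5 * ssr))
        st.a = np.sqrt(a_sq)

    def update_structural_params(self, st: McmcState, rng) -> None:
        pr = self.prior
        n, T = self.n, self.T
        counts = np.bincount(st.cls[:, 0], minlength=self.C) if n else np.zeros(self.C)
        st.pi = rng.dirichlet(pr.pi_conc + counts)
        dis_cells = st.d[:, self.t_of] == 1  # (N, J)
        if self.config.mixture:
            nd = float(st.d.sum())
            st.omega = rng.beta(pr.omega_a + nd, pr.omega_b + n * T - nd)
            n_corr = float(self.x[dis_cells].sum())
            n_cell = float(dis_cells.sum())
            st.gstar = float(np.clip(rng.beta(pr.gstar_a + n_corr,
                                              pr.gstar_b + n_cell - n_corr),
                                     1e-9, 1 - 1e-9))
            dis_logl = self.log_l[dis_cells]
            prec = 1.0 / pr.mu1_sd ** 2 + dis_logl.size / st.sigma1_sq
            mean = (pr.mu1_mean / pr.mu1_sd ** 2 + dis_logl.sum() / st.sigma1_sq) / prec
            st.mu1 = mean + rng.standard_normal() / np.sqrt(prec)
            sh = pr.sigma1_sq_shape + 0.5 * dis_logl.size
            rate = pr.sigma1_sq_scale + 0.5 * ((dis_logl - st.mu1) ** 2).sum()
            st.sigma1_sq = rate / rng.gamma(sh, 1.0)
        # phi: conjugate normal over engaged cells whose covariate G is 1
        engaged = st.d[:, self.t_of] == 0
        g_cells = self.eta[st.cls[:, self.t_of], self.item_index[None, :]].astype(bool)
        mask = engaged & g_cells
        a2_cells = np.broadcast_to((st.a ** 2)[None, :], mask.shape)[mask]
        obs = (st.gamma[None, :] - st.tau[:, None] - self.log_l)[mask]
        prec = 1.0 / pr.phi_sd ** 2 + a2_cells.sum()
        mean = (pr.phi_mean / pr.phi_sd ** 2 + (a2_cells * obs).sum()) / prec
        st.phi = mean + rng.standard_normal() / np.sqrt(prec)
        # initial-speed variance
        sh = pr.sigma_tau_sq_shape + 0.5 * n
        rate = pr.sigma_tau_sq_scale + 0.5 * (st.tau ** 2).sum()
        st.sigma_tau_sq = rate / rng.gamma(sh, 1.0)
        self._update_lambda(st, rng)
        self._recenter_speed_scale(st, rng)

    def _recenter_speed_scale(self, st, rng) -> None:
        """Translation move along the speed-scale ridge.

        The engaged RT likelihood depends on intensities and speeds only
        through gamma_j - tau_i, so it is invariant under a common shift
        (gamma + c, tau + c). Drawing c from its conditional under the
        priors is a Gibbs step on that orbit and removes the slow random
        walk of the two blocks against each other.
        """
        pr = self.prior
        prec = self.J / pr.gamma_sd ** 2 + self.n / st.sigma_tau_sq
        mean = ((pr.gamma_mean - st.gamma).sum() / pr.gamma_sd ** 2
                - st.tau.sum() / st.sigma_tau_sq) / prec
        c = mean + rng.standard_normal() / np.sqrt(prec)
        st.gamma = st.gamma + c
        st.tau = st.tau + c

    def _lambda_logpost(self, vec, st, m_t, m_t1, w):
        lam0, loglam1, loglam2 = vec
        lam1, lam2 = np.exp(loglam1), np.exp(loglam2)
        pr = self.prior
        prior = (-0.5 * ((lam0 - pr.lambda0_mean) / pr.lambda0_sd) ** 2
                 - 0.5 * ((loglam1 - pr.lambda1_logmean) / pr.lambda1_logsd) ** 2
                 - 0.5 * ((loglam2 - pr.lambda2_logmean) / pr.lambda2_logsd) ** 2)
        if m_t is None:
            return prior
        z = lam0 + lam1 * st.theta[:, None] + lam2 * m_t
        lp = (m_t1 - m_t) * _log_sigmoid(z) + (self.K - m_t1) * _log_sigmoid(-z)
        return prior + (lp * w).sum()

    def _update_lambda(self, st, rng) -> None:
        if self.n and self.T > 1:
            m_t, m_t1, w = self._transition_suffstats(st)
        else:
            m_t = m_t1 = w = None
        vec = np.array([st.lambda0, np.log(st.lambda1), np.log(st.lambda2)])
        cur = self._lambda_logpost(vec, st, m_t, m_t1, w)
        for _ in range(self.config.lambda_steps):
            prop = vec + self.lambda_scale * rng.standard_normal(3)
            new = self._lambda_logpost(prop, st, m_t, m_t1, w)
            acc = np.log(rng.random()) < new - cur
            if acc:
                vec, cur = prop, new
            self._acc["lambda"] += acc
            self._acc["lambda_n"] += 1
            self._win["lambda"] += acc
            self._win["lambda_n"] += 1
        st.lambda0 = float(vec[0])
        st.lambda1 = float(np.exp(vec[1]))
        st.lambda2 = float(np.exp(vec[2]))

    def _adapt_scales(self) -> None:
        w = self._win
        if w["theta_n"] > 0:
            rate = w["theta"] / w["theta_n"]
            if rate < 0.2:
                self.theta_scale *= 0.8
            elif rate > 0.5:
                self.theta_scale *= 1.25
        if w["lambda_n"] > 0:
            rate = w["lambda"] / w["lambda_n"]
            if rate < 0.2:
                self.lambda_scale *= 0.8
            elif rate > 0.5:
                self.lambda_scale *= 1.25
        for k in w:
            w[k] = 0.0

    def sweep(self, st: McmcState, rng, tables=None) -> None:
        """One full Gibbs cycle: latents -> person -> item -> structural,
        with the latent/person pair refreshed ``1 + extra_latent_sweeps``
        times per cycle."""
        self.update_latents(st, rng, tables=tables)
        self.update_person_params(st, rng)
        for _ in range(self.config.extra_latent_sweeps):
            self.update_latents(st, rng)
            self.update_person_params(st, rng)
        self.update_item_params(st, rng)
        self.update_structural_params(st, rng)


def run_mcmc(data: ObservedData, config: McmcConfig, seed=None) -> McmcSamples:
    """Run one chain and store full-length draws.

    The stored deviance at sweep ``it`` is evaluated on the state left by
    sweep ``it - 1`` (parameters and latents jointly), which is an
    equally-valid stationary draw and avoids recomputing likelihood tables.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = GibbsSampler(data, config)
    st = init_chain(data, config, rng)
    n, T, K, J, C = sampler.n, sampler.T, sampler.K, sampler.J, sampler.C
    draws, burn = config.draws, config.burn
    structural = {k: np.empty(draws) for k in STRUCTURAL_FIELDS}
    pi_tr = np.empty((draws, C))
    item = {k: np.empty((draws, J)) for k in ("s", "g", "gamma", "a")}
    person = ({k: np.empty((draws, n)) for k in ("theta", "tau")}
              if config.store_person else {})
    deviance = np.empty(draws)
    alpha_freq = np.zeros((n, T, K))
    d_freq = np.zeros((n, T))
    n_post = 0
    n_snap = min(config.n_ppc_snapshots, draws - burn)
    snap_iters = set(np.linspace(burn, draws - 1, n_snap).astype(int).tolist()) if n_snap else set()
    snapshots = []
    for it in range(draws):
        tables = sampler.measurement_tables(st)
        dev = sampler.deviance(st, tables)
        if not np.isfinite(dev):
            raise RuntimeError(
                f"non-finite deviance at sweep {it}; state dump: "
                f"omega={st.omega}, gstar={st.gstar}, sigma1_sq={st.sigma1_sq}")
        deviance[it] = dev
        sampler.sweep(st, rng, tables=tables)
        for k in STRUCTURAL_FIELDS:
            structural[k][it] = getattr(st, k)
        pi_tr[it] = st.pi
        for k in item:
            item[k][it] = getattr(st, k)
        if config.store_person:
            person["theta"][it] = st.theta
            person["tau"][it] = st.tau
        if it >= burn:
            alpha_freq += sampler.profiles[st.cls]
            d_freq += st.d
            n_post += 1
            if it in snap_iters:
                snapshots.append(dict(
                    cls=st.cls.copy(), d=st.d.copy(), tau=st.tau.copy(),
                    s=st.s.copy(), g=st.g.copy(), gamma=st.gamma.copy(),
                    a=st.a.copy(), gstar=st.gstar, mu1=st.mu1,
                    sigma1_sq=st.sigma1_sq, phi=st.phi))
        if config.adapt and it < burn and (it + 1) % config.adapt_window == 0:
            sampler._adapt_scales()
    if n_post:
        alpha_freq /= n_post
        d_freq /= n_post
    acc = {
        "theta": (sampler._acc["theta"] / sampler._acc["theta_n"]
                  if sampler._acc["theta_n"] else float("nan")),
        "lambda": (sampler._acc["lambda"] / sampler._acc["lambda_n"]
                   if sampler._acc["lambda_n"] else float("nan")),
    }
    return McmcSamples(structural=structural, pi=pi_tr, item=item, person=person,
                       deviance=deviance, alpha_freq=alpha_freq, d_freq=d_freq,
                       snapshots=snapshots, burn=burn,
                       seed=seed if isinstance(seed, int) else None,
                       acceptance=acc, config=config)


def run_chains(data: ObservedData, config: McmcConfig, seed=None) -> list[McmcSamples]:
    """Run ``config.chains`` independent chains with spawned seeds."""
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    return [run_mcmc(data, config, seed=np.random.default_rng(child))
            for child in ss.spawn(config.chains)]


@dataclass
class PosteriorSummary:
    """EAP point estimates, posterior SDs, and dichotomized latent states."""

    structural: dict  # name -> (eap, sd)
    pi: np.ndarray
    pi_sd: np.ndarray
    item: ItemParams
    item_sd: dict
    person: PersonParams
    person_sd: dict
    alpha_freq: np.ndarray
    alpha_hat: np.ndarray  # (N, T, K), dichotomized at 0.5 (ties -> 0)
    d_freq: np.ndarray
    d_hat: np.ndarray

    def structural_params(self) -> StructuralParams:
        e = {k: v[0] for k, v in self.structural.items()}
        return StructuralParams(pi=self.pi, **{k: e[k] for k in STRUCTURAL_FIELDS})


def posterior_summaries(samples: McmcSamples | list[McmcSamples]) -> PosteriorSummary:
    """Pool post-burn-in draws (across chains, if several) into EAPs/SDs.

    The discrete latent states are dichotomized at posterior inclusion
    frequency 0.5, with exact ties resolved to 0 (non-mastery / engaged).
    """
    chains = samples if isinstance(samples, list) else [samples]
    if not chains or chains[0].draws == 0:
        raise DomainError("posterior summary requires a non-empty sample")
    post = {k: np.concatenate([c.structural[k][c.burn:] for c in chains])
            for k in STRUCTURAL_FIELDS}
    if post["lambda0"].size == 0:
        raise DomainError("no post-burn-in draws available")
    structural = {k: (float(v.mean()), float(v.std())) for k, v in post.items()}
    pi_draws = np.concatenate([c.pi[c.burn:] for c in chains])
    item_draws = {k: np.concatenate([c.item[k][c.burn:] for c in chains])
                  for k in chains[0].item}
    item_eap = {k: v.mean(axis=0) for k, v in item_draws.items()}
    # order constraint can fail for the raw EAP pair; nudge if needed
    eps = 1e-9
    item_eap["g"] = np.minimum(item_eap["g"], 1.0 - item_eap["s"] - eps)
    item = ItemParams(s=item_eap["s"], g=item_eap["g"],
                      gamma=item_eap["gamma"], a=item_eap["a"])
    item_sd = {k: v.std(axis=0) for k, v in item_draws.items()}
    if chains[0].person:
        per_draws = {k: np.concatenate([c.person[k][c.burn:] for c in chains])
                     for k in chains[0].person}
        person = PersonParams(theta=per_draws["theta"].mean(axis=0),
                              tau=per_draws["tau"].mean(axis=0))
        person_sd = {k: v.std(axis=0) for k, v in per_draws.items()}
    else:
        person = PersonParams(theta=np.zeros(0), tau=np.zeros(0))
        person_sd = {}
    alpha_freq = np.mean([c.alpha_freq for c in chains], axis=0)
    d_freq = np.mean([c.d_freq for c in chains], axis=0)
    return PosteriorSummary(
        structural=structural, pi=pi_draws.mean(axis=0), pi_sd=pi_draws.std(axis=0),
        item=item, item_sd=item_sd, person=person, person_sd=person_sd,
        alpha_freq=alpha_freq, alpha_hat=(alpha_freq > 0.5).astype(np.int8),
        d_freq=d_freq, d_hat=(d_freq > 0.5).astype(np.int8))
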
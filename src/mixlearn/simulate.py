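"""Synthetic data generation for the mixture learning model.

The default design mirrors the spatial-rotation learning experiment that
motivates the model: N learners, K = 4 binary rotation skills, T = 4
modules of 10 items each, and true parameters set to the posterior-mean
estimates from that study (40 items' slipping/guessing/time parameters,
transition coefficients, a disengaged rapid-guessing component with
g* = 0.503 and log-RT law N(2.528, 1.158), and disengagement probability
omega of 0.03 or 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import enumerate_profiles, eta_table, profile_index
from .types import (
    DomainError,
    ItemParams,
    LatentState,
    ObservedData,
    PersonParams,
    QMatrix,
    StructuralParams,
)

# Posterior-mean item parameter estimates from the spatial rotation learning
# experiment (40 items: modules 1-4, ten items each): slipping, guessing,
# time discrimination, time intensity.
REFERENCE_ITEMS = np.array([
    # s      g      a      gamma
    [0.045, 0.811, 1.410, 2.312],
    [0.086, 0.737, 1.776, 2.940],
    [0.082, 0.699, 1.865, 3.371],
    [0.224, 0.635, 1.679, 3.762],
    [0.140, 0.484, 1.781, 3.452],
    [0.223, 0.570, 1.702, 3.476],
    [0.195, 0.355, 1.869, 3.510],
    [0.195, 0.530, 1.737, 3.658],
    [0.299, 0.379, 1.735, 3.687],
    [0.279, 0.378, 1.533, 3.612],
    [0.019, 0.876, 2.103, 2.671],
    [0.011, 0.943, 2.271, 2.594],
    [0.037, 0.842, 2.113, 2.601],
    [0.088, 0.843, 2.150, 2.464],
    [0.106, 0.855, 2.155, 2.187],
    [0.064, 0.585, 1.820, 3.040],
    [0.095, 0.498, 2.011, 3.019],
    [0.060, 0.783, 1.975, 2.854],
    [0.089, 0.658, 1.723, 3.135],
    [0.119, 0.613, 1.655, 3.179],
    [0.032, 0.798, 1.848, 2.630],
    [0.220, 0.317, 1.769, 3.292],
    [0.329, 0.405, 1.947, 2.979],
    [0.135, 0.429, 1.500, 3.173],
    [0.257, 0.421, 2.099, 2.904],
    [0.146, 0.261, 1.817, 3.333],
    [0.215, 0.392, 1.732, 3.509],
    [0.361, 0.370, 1.810, 3.395],
    [0.483, 0.327, 1.749, 3.289],
    [0.532, 0.273, 1.743, 3.271],
    [0.063, 0.756, 2.108, 2.622],
    [0.035, 0.825, 2.106, 2.264],
    [0.033, 0.892, 1.867, 2.736],
    [0.227, 0.458, 1.701, 3.241],
    [0.141, 0.537, 1.727, 3.075],
    [0.205, 0.520, 1.780, 3.498],
    [0.232, 0.345, 1.546, 3.492],
    [0.274, 0.366, 1.662, 3.299],
    [0.494, 0.171, 1.373, 3.439],
    [0.254, 0.285, 1.368, 3.206],
])

# Transition-model and RT-covariate estimates from the same study.
REFERENCE_LAMBDA = (-2.214, 2.757, 0.286)
REFERENCE_PHI = -0.332
REFERENCE_GSTAR = 0.503
REFERENCE_MU1 = 2.528
REFERENCE_SIGMA1_SQ = 1.158
REFERENCE_FULL_MASTERY_PI = 0.527
# Prior-mean default for the unreported initial-speed variance.
DEFAULT_SIGMA_TAU_SQ = 2.0 / 3.0
# Fixed seed for the packaged default Q-matrix (10 items per module, K=4).
DEFAULT_Q_SEED = 1729


def reference_item_params() -> ItemParams:
    """The 40-item reference parameters as an :class:`ItemParams`."""
    t = REFERENCE_ITEMS
    return ItemParams(s=t[:, 0].copy(), g=t[:, 1].copy(), a=t[:, 2].copy(),
                      gamma=t[:, 3].copy())


def reference_pi(n_skills: int = 4,
                 full_mastery_mass: float = REFERENCE_FULL_MASTERY_PI) -> np.ndarray:
    """Initial profile distribution: the reported full-mastery share, with the
    remaining mass spread uniformly over the other 2^K - 1 profiles."""
    c = 2 ** n_skills
    pi = np.full(c, (1.0 - full_mastery_mass) / (c - 1))
    pi[-1] = full_mastery_mass
    return pi


def reference_structural_params(omega: float = 0.03,
                                sigma_tau_sq: float = DEFAULT_SIGMA_TAU_SQ,
                                n_skills: int = 4) -> StructuralParams:
    """Reference population parameters at the given disengagement rate."""
    lam0, lam1, lam2 = REFERENCE_LAMBDA
    return StructuralParams(
        lambda0=lam0, lambda1=lam1, lambda2=lam2,
        pi=reference_pi(n_skills), omega=omega,
        gstar=REFERENCE_GSTAR, mu1=REFERENCE_MU1, sigma1_sq=REFERENCE_SIGMA1_SQ,
        phi=REFERENCE_PHI, sigma_tau_sq=sigma_tau_sq,
    )


def generate_q_matrix(n_items: int, n_skills: int, seed: int) -> QMatrix:
    """Balanced binary Q-matrix.

    The first K rows are the K single-skill items (completeness, needed for
    identifiability of the profiles). Remaining rows alternate between
    one- and two-skill items, always targeting the currently least-measured
    skills with seeded random tie-breaking. The result is deterministic
    under the seed, and skill coverage stays balanced: every skill is
    measured at least twice whenever ``n_items >= 2 * n_skills``.
    """
    if n_items < n_skills:
        raise DomainError("need at least as many items as skills for completeness")
    rng = np.random.default_rng(seed)
    rows = [np.eye(n_skills, dtype=np.int8)[k] for k in range(n_skills)]
    counts = np.ones(n_skills)
    for r in range(n_items - n_skills):
        jitter = rng.random(n_skills) * 1e-6  # seeded tie-break
        order = np.argsort(counts + jitter)
        row = np.zeros(n_skills, dtype=np.int8)
        n_req = 1 if r % 2 == 0 else min(2, n_skills)
        row[order[:n_req]] = 1
        counts += row
        rows.append(row)
    return QMatrix(np.array(rows))


def default_q_matrix(n_times: int = 4, items_per_time: int = 10,
                     n_skills: int = 4, seed: int = DEFAULT_Q_SEED) -> tuple[QMatrix, np.ndarray]:
    """Packaged default Q-matrix: one complete balanced block per module.

    Returns the stacked Q-matrix and the item -> module assignment.
    """
    blocks = [generate_q_matrix(items_per_time, n_skills, seed + t).q
              for t in range(n_times)]
    q = QMatrix(np.vstack(blocks))
    item_time = np.repeat(np.arange(n_times), items_per_time)
    return q, item_time


def sample_initial_profiles(pi: np.ndarray, n: int, seed) -> np.ndarray:
    """IID draws of initial profiles from the class simplex ``pi``; (n, K)."""
    pi = np.asarray(pi, dtype=float)
    if (pi < 0).any() or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise DomainError("pi must be a probability simplex")
    k = int(np.log2(pi.shape[0]))
    if 2 ** k != pi.shape[0]:
        raise DomainError("pi length must be a power of two")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cls = rng.choice(pi.shape[0], size=n, p=pi / pi.sum())
    return enumerate_profiles(k)[cls].copy()


@dataclass
class SimDesign:
    """Design of one simulated study.

    Defaults reproduce the reference condition: N = 585 learners, K = 4
    skills, T = 4 modules of 10 items, reference item and structural truth,
    theta ~ N(0, 1) and tau ~ N(0, sigma_tau_sq).
    """

    n_learners: int = 585
    n_skills: int = 4
    n_times: int = 4
    items_per_time: int = 10
    omega: float = 0.03
    seed: int = 0
    q: QMatrix | None = None
    item_time: np.ndarray | None = None
    item_params: ItemParams | None = None
    structural: StructuralParams | None = None

    def __post_init__(self) -> None:
        if min(self.n_learners, self.n_skills, self.n_times, self.items_per_time) < 1:
            raise DomainError("all design counts must be >= 1")
        if self.q is None:
            self.q, self.item_time = default_q_matrix(
                self.n_times, self.items_per_time, self.n_skills)
        elif self.item_time is None:
            raise DomainError("item_time must accompany a supplied Q-matrix")
        if self.item_params is None:
            if self.q.n_items == 40:
                self.item_params = reference_item_params()
            else:
                raise DomainError("item_params required for non-default item banks")
        if self.structural is None:
            self.structural = reference_structural_params(
                omega=self.omega, n_skills=self.n_skills)


@dataclass
class SimResult:
    """A simulated dataset together with its generating truth."""

    data: ObservedData
    latent: LatentState
    item_params: ItemParams
    person_params: PersonParams
    structural: StructuralParams
    seed: int


def simulate_dataset(design: SimDesign) -> SimResult:
    """Draw one dataset under the mixture learning model.

    Modes are IID Bernoulli(omega) over learner-module cells; engaged
    transitions follow the monotone higher-order logistic model while
    disengaged modules freeze the profile; responses and response times
    follow the mode-conditional measurement laws.
    """
    rng = np.random.default_rng(design.seed)
    n, K, T = design.n_learners, design.n_skills, design.n_times
    st = design.structural
    items = design.item_params
    qm = design.q
    item_time = np.asarray(design.item_time)
    J = qm.n_items

    theta = rng.standard_normal(n)
    tau = rng.normal(0.0, np.sqrt(st.sigma_tau_sq), size=n)
    d = (rng.random((n, T)) < st.omega).astype(np.int8)

    alpha = np.zeros((n, T, K), dtype=np.int8)
    alpha[:, 0] = sample_initial_profiles(st.pi, n, rng)
    for t in range(T - 1):
        cur = alpha[:, t]
        m = cur.sum(axis=1)
        # engaged: each unmastered skill acquired with the higher-order prob
        z = st.lambda0 + st.lambda1 * theta + st.lambda2 * m
        p = 1.0 / (1.0 + np.exp(-z))
        gains = (rng.random((n, K)) < p[:, None]) & (cur == 0)
        nxt = np.where(gains, 1, cur).astype(np.int8)
        frozen = d[:, t] == 1
        nxt[frozen] = cur[frozen]
        alpha[:, t + 1] = nxt

    eta = eta_table(qm.q)  # (C, J)
    cls = profile_index(alpha)  # (N, T)
    eta_cells = eta[cls[:, item_time], np.arange(J)[None, :]]  # (N, J)
    dis = d[:, item_time].astype(bool)

    p_correct = np.where(dis, st.gstar,
                         np.where(eta_cells == 1, 1.0 - items.s[None, :],
                                  items.g[None, :]))
    x = (rng.random((n, J)) < p_correct).astype(np.int8)

    mean_eng = items.gamma[None, :] - (tau[:, None] + st.phi * eta_cells)
    sd_eng = 1.0 / items.a[None, :]
    log_l = np.where(dis,
                     rng.normal(st.mu1, np.sqrt(st.sigma1_sq), size=(n, J)),
                     rng.normal(0.0, 1.0, size=(n, J)) * sd_eng + mean_eng)
    data = ObservedData(x=x, latency=np.exp(log_l), item_time=item_time, q=qm)
    latent = LatentState(alpha=alpha, d=d)
    latent.validate()
    return SimResult(data=data, latent=latent, item_params=items,
                     person_params=PersonParams(theta=theta, tau=tau),
                     structural=st, seed=design.seed)
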
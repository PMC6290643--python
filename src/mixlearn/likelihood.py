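"""Mode-conditional probability components and the complete-data log-likelihood.

Engaged learners (D = 0) answer through a DINA measurement model, take
log-normal response times centred at ``gamma_j - (tau_i + phi * G)``, and
may acquire skills between modules through a higher-order logistic
transition. Disengaged learners (D = 1) rapid-guess: every response is
correct with probability g*, log response times are N(mu1, sigma1_sq), and
the skill profile is frozen.
"""

from __future__ import annotations

import numpy as np

from .types import (
    DimensionError,
    DomainError,
    ItemParams,
    LatentState,
    ObservedData,
    PersonParams,
    StructuralParams,
)

_LOG_2PI = float(np.log(2.0 * np.pi))


def enumerate_profiles(n_skills: int) -> np.ndarray:
    """All 2^K binary skill profiles, ordered by their integer encoding.

    Profile c has bit k equal to ``(c >> k) & 1``, so the all-zero profile
    is index 0 and the full-mastery profile is index 2^K - 1.
    """
    c = np.arange(2 ** n_skills)
    return ((c[:, None] >> np.arange(n_skills)[None, :]) & 1).astype(np.int8)


def profile_index(alpha: np.ndarray) -> np.ndarray:
    """Integer class encoding of binary profiles along the last axis."""
    alpha = np.asarray(alpha)
    weights = 1 << np.arange(alpha.shape[-1])
    return (alpha * weights).sum(axis=-1).astype(np.int64)


def ideal_response(alpha, q_row) -> int:
    """DINA ideal response: 1 iff every skill the item requires is mastered."""
    alpha = np.asarray(alpha)
    q_row = np.asarray(q_row)
    if alpha.shape != q_row.shape:
        raise DimensionError("profile and Q-row must have the same length")
    return int((alpha >= q_row).all())


def speed_covariate(alpha, q_row) -> int:
    """Speed covariate G: 1 iff the profile dominates the item's Q-row.

    Numerically identical to :func:`ideal_response`; kept as its own entry
    point because it feeds the response-time mean rather than the response
    probability.
    """
    return ideal_response(alpha, q_row)


def eta_table(q: np.ndarray) -> np.ndarray:
    """Ideal responses for every (profile class, item) pair, shape (2^K, J)."""
    q = np.asarray(q)
    profiles = enumerate_profiles(q.shape[1])
    return (profiles[:, None, :] >= q[None, :, :]).all(axis=2).astype(np.int8)


def response_prob(mode: int, eta: int, s: float | None = None,
                  g: float | None = None, gstar: float | None = None) -> float:
    """Probability of a correct response, conditional on the engagement mode."""
    if mode not in (0, 1):
        raise DomainError("mode must be 0 (engaged) or 1 (disengaged)")
    if mode == 1:
        if gstar is None or not 0.0 < gstar < 1.0:
            raise DomainError("gstar must lie in (0, 1)")
        return float(gstar)
    if s is None or g is None or not (0.0 < s < 1.0 and 0.0 < g < 1.0):
        raise DomainError("s and g must lie in (0, 1)")
    return float(1.0 - s) if eta else float(g)


def rt_logdensity(mode: int, latency: float, gamma: float = 0.0, a: float = 1.0,
                  tau: float = 0.0, phi: float = 0.0, G: int = 0,
                  mu1: float = 0.0, sigma1_sq: float = 1.0) -> float:
    """Log-density of a response time under the mode-appropriate log-normal law.

    Engaged: log L ~ N(gamma - (tau + phi * G), 1 / a^2).
    Disengaged: log L ~ N(mu1, sigma1_sq).
    The returned value is the density of L itself (includes the 1/L Jacobian).
    """
    latency = float(latency)
    if latency <= 0:
        raise DomainError("latency must be positive")
    log_l = np.log(latency)
    if mode == 1:
        if sigma1_sq <= 0:
            raise DomainError("sigma1_sq must be positive")
        z2 = (log_l - mu1) ** 2 / sigma1_sq
        return float(-0.5 * (_LOG_2PI + np.log(sigma1_sq)) - 0.5 * z2 - log_l)
    if a <= 0:
        raise DomainError("time discrimination a must be positive")
    mean = gamma - (tau + phi * G)
    return float(np.log(a) - 0.5 * _LOG_2PI - 0.5 * a * a * (log_l - mean) ** 2 - log_l)


def skill_transition_prob(theta: float, n_other_mastered: int, lambda0: float,
                          lambda1: float, lambda2: float) -> float:
    """Per-skill non-mastery -> mastery probability for an engaged learner.

    logistic(lambda0 + lambda1 * theta + lambda2 * #other mastered skills).
    """
    z = lambda0 + lambda1 * theta + lambda2 * n_other_mastered
    # logistic via expit-stable form
    if z >= 0:
        return float(1.0 / (1.0 + np.exp(-z)))
    ez = np.exp(z)
    return float(ez / (1.0 + ez))


def profile_transition_prob(alpha_t, alpha_next, theta: float, d_t: int,
                            lambdas: tuple[float, float, float]) -> float:
    """One-step transition probability of the whole profile.

    Disengaged (d_t = 1): the profile is frozen, so the probability is the
    indicator of equality. Engaged: forgetting has probability zero, and the
    unmastered skills transition independently with the higher-order logistic
    probability (other-mastery count taken at time t).
    """
    alpha_t = np.asarray(alpha_t)
    alpha_next = np.asarray(alpha_next)
    if alpha_t.shape != alpha_next.shape:
        raise DimensionError("profiles must have the same length")
    if d_t == 1:
        return float(np.array_equal(alpha_t, alpha_next))
    if (alpha_next < alpha_t).any():
        return 0.0
    lam0, lam1, lam2 = lambdas
    prob = 1.0
    m = int(alpha_t.sum())
    for k in range(alpha_t.shape[0]):
        if alpha_t[k] == 1:
            continue
        p = skill_transition_prob(theta, m, lam0, lam1, lam2)
        prob *= p if alpha_next[k] == 1 else (1.0 - p)
    return float(prob)


def _measurement_loglik(data: ObservedData, cls: np.ndarray, d: np.ndarray,
                        items: ItemParams, persons: PersonParams,
                        structural: StructuralParams) -> float:
    """Response + RT log-likelihood given latent classes and modes.

    This is the deviance kernel: transition, initial-class and mode terms
    are excluded. ``cls`` is the (N, T) integer profile encoding.
    """
    eta = eta_table(data.q.q)  # (C, J)
    t_of = data.item_time
    eta_cells = eta[cls[:, t_of], np.arange(data.n_items)[None, :]]  # (N, J)
    dis = d[:, t_of].astype(bool)

    x = data.x
    log_l = np.log(data.latency)
    # engaged response
    p1 = np.where(eta_cells == 1, 1.0 - items.s[None, :], items.g[None, :])
    resp_eng = x * np.log(p1) + (1 - x) * np.log1p(-p1)
    resp_dis = x * np.log(structural.gstar) + (1 - x) * np.log1p(-structural.gstar)
    # engaged RT
    mean_eng = items.gamma[None, :] - (persons.tau[:, None] + structural.phi * eta_cells)
    rt_eng = (np.log(items.a)[None, :] - 0.5 * _LOG_2PI
              - 0.5 * (items.a[None, :] ** 2) * (log_l - mean_eng) ** 2 - log_l)
    rt_dis = (-0.5 * (_LOG_2PI + np.log(structural.sigma1_sq))
              - 0.5 * (log_l - structural.mu1) ** 2 / structural.sigma1_sq - log_l)
    total = np.where(dis, resp_dis + rt_dis, resp_eng + rt_eng)
    return float(total.sum())


def complete_data_loglik(data: ObservedData, latent: LatentState,
                         items: ItemParams, persons: PersonParams,
                         structural: StructuralParams) -> float:
    """Joint log-probability of data and latent states given all parameters.

    Sums the initial-class term, the Bernoulli(omega) mode terms, the
    mode-conditional transition terms, and the measurement terms. States
    violating the frozen/monotone invariants return -inf.
    """
    try:
        latent.validate()
    except DomainError:
        return float(-np.inf)
    cls = profile_index(latent.alpha)
    n, T = latent.d.shape
    ll = 0.0
    with np.errstate(divide="ignore"):
        log_pi = np.log(structural.pi)
    if np.isneginf(log_pi[cls[:, 0]]).any():
        return float(-np.inf)
    ll += float(log_pi[cls[:, 0]].sum())
    om = structural.omega
    nd = int(latent.d.sum())
    if 0.0 < om < 1.0:
        ll += nd * np.log(om) + (n * T - nd) * np.log1p(-om)
    elif (om == 0.0 and nd > 0) or (om == 1.0 and nd < n * T):
        return float(-np.inf)
    lams = (structural.lambda0, structural.lambda1, structural.lambda2)
    for i in range(n):
        for t in range(T - 1):
            p = profile_transition_prob(latent.alpha[i, t], latent.alpha[i, t + 1],
                                        persons.theta[i], int(latent.d[i, t]), lams)
            if p <= 0.0:
                return float(-np.inf)
            ll += float(np.log(p))
    ll += _measurement_loglik(data, cls, latent.d, items, persons, structural)
    return float(ll)
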
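"""Core domain containers for the mixture learning model.

The model follows N learners over T time points (modules). At each time
point a learner holds a binary skill profile ``alpha`` (K skills) and a
binary engagement mode ``D`` (0 = engaged, 1 = disengaged). Items measure
skills through a binary Q-matrix; each item yields a correct/incorrect
response and a response time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DimensionError(ValueError):
    """Raised when array dimensions are inconsistent."""


class DomainError(ValueError):
    """Raised when a value lies outside its parameter space."""


def _as_binary(arr, name: str) -> np.ndarray:
    out = np.asarray(arr)
    if not np.isin(out, (0, 1)).all():
        raise DomainError(f"{name} must be binary (0/1)")
    return out.astype(np.int8)


@dataclass
class QMatrix:
    """Binary item-by-skill requirement matrix.

    ``q[j, k] = 1`` when item j requires skill k. Every item must require
    at least one skill.
    """

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = _as_binary(self.q, "Q-matrix")
        if self.q.ndim != 2:
            raise DimensionError("Q-matrix must be 2-dimensional (items x skills)")
        if self.q.shape[1] < 1:
            raise DimensionError("Q-matrix needs at least one skill column")
        if (self.q.sum(axis=1) < 1).any():
            raise DomainError("every item must require at least one skill")

    @property
    def n_items(self) -> int:
        return self.q.shape[0]

    @property
    def n_skills(self) -> int:
        return self.q.shape[1]


@dataclass
class ObservedData:
    """Responses and latencies for N learners on items grouped into T modules.

    Responses ``x`` and latencies ``latency`` are (N, J) arrays over the full
    item bank; ``item_time[j]`` gives the 0-based module of item j (the
    module partition of the bank), so unequal numbers of items per module
    are supported.
    """

    x: np.ndarray
    latency: np.ndarray
    item_time: np.ndarray
    q: QMatrix

    def __post_init__(self) -> None:
        self.x = _as_binary(self.x, "responses")
        self.latency = np.asarray(self.latency, dtype=float)
        self.item_time = np.asarray(self.item_time, dtype=np.int64)
        if self.x.ndim != 2 or self.latency.shape != self.x.shape:
            raise DimensionError("responses and latencies must share an (N, J) shape")
        if self.x.shape[1] != self.q.n_items or self.item_time.shape != (self.x.shape[1],):
            raise DimensionError("item axis of data, Q-matrix and item_time disagree")
        if self.x.size and not (self.latency > 0).all():
            raise DomainError("latencies must be strictly positive seconds")
        times = np.unique(self.item_time)
        if self.x.shape[1] and not np.array_equal(times, np.arange(times.size)):
            raise DomainError("item_time must cover 0..T-1 contiguously")

    @property
    def n_learners(self) -> int:
        return self.x.shape[0]

    @property
    def n_times(self) -> int:
        return int(self.item_time.max()) + 1 if self.item_time.size else 0

    @property
    def n_items(self) -> int:
        return self.x.shape[1]

    @property
    def n_skills(self) -> int:
        return self.q.n_skills

    def items_at(self, t: int) -> np.ndarray:
        """Column indices of the items administered at module ``t``."""
        return np.flatnonzero(self.item_time == t)


@dataclass
class LatentState:
    """Per-learner latent trajectory: skill profiles and engagement modes.

    Invariants: a disengaged time point freezes the profile
    (``D[i,t] = 1`` implies ``alpha[i,t+1] == alpha[i,t]``), and engaged
    transitions never lose a mastered skill (monotone growth).
    """

    alpha: np.ndarray  # (N, T, K) binary
    d: np.ndarray  # (N, T) binary

    def __post_init__(self) -> None:
        self.alpha = _as_binary(self.alpha, "alpha")
        self.d = _as_binary(self.d, "D")
        if self.alpha.ndim != 3 or self.d.shape != self.alpha.shape[:2]:
            raise DimensionError("alpha must be (N, T, K) and D (N, T)")

    def validate(self) -> None:
        """Raise DomainError if the frozen/monotone invariants are violated."""
        a, d = self.alpha, self.d
        if a.shape[1] < 2:
            return
        diff = a[:, 1:, :].astype(int) - a[:, :-1, :].astype(int)
        frozen = d[:, :-1] == 1
        if (np.abs(diff[frozen]) > 0).any():
            raise DomainError("disengaged time point must freeze the profile")
        if (diff[~frozen] < 0).any():
            raise DomainError("engaged transition may not lose a mastered skill")


@dataclass
class ItemParams:
    """DINA slipping/guessing and log-normal response-time item parameters."""

    s: np.ndarray
    g: np.ndarray
    gamma: np.ndarray  # time intensity, log-seconds
    a: np.ndarray  # time discrimination (> 0)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if not (self.s.shape == self.g.shape == self.gamma.shape == self.a.shape):
            raise DimensionError("item parameter vectors must share one shape")
        if self.s.size:
            if not ((self.g >= 0) & (self.g < 1 - self.s) & (self.s >= 0) & (1 - self.s <= 1)).all():
                raise DomainError("item parameters must satisfy 0 <= g < 1 - s <= 1")
            if not (self.a > 0).all():
                raise DomainError("time discriminations must be positive")

    @property
    def n_items(self) -> int:
        return self.s.shape[0]


@dataclass
class PersonParams:
    """Learner-level latent traits: learning ability theta, initial speed tau."""

    theta: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.theta.shape != self.tau.shape:
            raise DimensionError("theta and tau must share one shape")
        if self.theta.size and not (np.isfinite(self.theta).all() and np.isfinite(self.tau).all()):
            raise DomainError("person parameters must be finite")


@dataclass
class StructuralParams:
    """Population-level parameters.

    lambda0/lambda1/lambda2 drive the higher-order skill-transition logit;
    ``pi`` is the initial distribution over the 2^K profiles; ``omega`` the
    disengagement probability; ``gstar`` the disengaged correct-response
    probability; (mu1, sigma1_sq) the disengaged log-RT law; ``phi`` the
    speed shift once an item's required skills are mastered; sigma_tau_sq
    the variance of initial speed.
    """

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

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise DomainError("lambda1 and lambda2 must be positive")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8) or (self.pi < 0).any():
            raise DomainError("pi must be a probability simplex")
        if not (0.0 <= self.omega <= 1.0):
            raise DomainError("omega must lie in [0, 1]")
        if not (0.0 < self.gstar < 1.0):
            raise DomainError("gstar must lie in (0, 1)")
        if self.sigma1_sq <= 0 or self.sigma_tau_sq <= 0:
            raise DomainError("variance parameters must be positive")

    @property
    def n_classes(self) -> int:
        return self.pi.shape[0]


@dataclass
class PriorSpec:
    """Hyperparameters of the prior layer.

    The slipping/guessing Beta hyperparameters default to 1 (uniform on the
    order-constrained region). ``lambda2_sd`` defaults to 0.6 (log-scale
    standard deviation); set ``lambda2_variance_literal=True`` to read the
    second log-normal argument as a variance of 0.62 instead.
    """

    a_s: float = 1.0
    b_s: float = 1.0
    a_g: float = 1.0
    b_g: float = 1.0
    omega_a: float = 1.0
    omega_b: float = 1.0
    gstar_a: float = 1.0
    gstar_b: float = 1.0
    pi_conc: float = 1.0
    lambda0_mean: float = 0.0
    lambda0_sd: float = 1.0
    lambda1_logmean: float = 0.5
    lambda1_logsd: float = 1.0
    lambda2_logmean: float = -0.5
    lambda2_sd: float = 0.6
    lambda2_variance_literal: bool = False
    gamma_mean: float = 0.0
    gamma_sd: float = 1.0
    phi_mean: float = 0.0
    phi_sd: float = 1.0
    a_sq_shape: float = 1.0
    a_sq_rate: float = 1.0
    mu1_mean: float = 0.0
    mu1_sd: float = 1.0
    sigma1_sq_shape: float = 1.0
    sigma1_sq_scale: float = 1.0
    sigma_tau_sq_shape: float = 2.5
    sigma_tau_sq_scale: float = 1.0

    def __post_init__(self) -> None:
        for name, val in self.__dict__.items():
            if name == "lambda2_variance_literal":
                continue
            if name in ("lambda0_mean", "lambda1_logmean", "lambda2_logmean",
                        "gamma_mean", "phi_mean", "mu1_mean"):
                continue  # location hyperparameters may be any real
            if val <= 0:
                raise DomainError(f"prior hyperparameter {name} must be positive")

    @property
    def lambda2_logsd(self) -> float:
        if self.lambda2_variance_literal:
            return float(np.sqrt(0.62))
        return self.lambda2_sd
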
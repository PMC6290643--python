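import numpy as np
import pytest

from mixlearn.likelihood import enumerate_profiles
from mixlearn.sampler import McmcState
from mixlearn.types import (
    ItemParams,
    ObservedData,
    PersonParams,
    QMatrix,
    StructuralParams,
)


@pytest.fixture
def tiny_k1_data():
    """One learner, K=1 skill, T=2 modules with one item each."""
    q = QMatrix(np.array([[1], [1]]))
    return ObservedData(
        x=np.array([[1, 0]]),
        latency=np.array([[8.0, 11.0]]),
        item_time=np.array([0, 1]),
        q=q,
    )


@pytest.fixture
def tiny_k1_params():
    items = ItemParams(s=np.array([0.1, 0.2]), g=np.array([0.3, 0.25]),
                       gamma=np.array([2.5, 2.2]), a=np.array([1.5, 2.0]))
    persons = PersonParams(theta=np.array([0.3]), tau=np.array([-0.2]))
    structural = StructuralParams(
        lambda0=-0.5, lambda1=1.0, lambda2=0.5, pi=np.array([0.6, 0.4]),
        omega=0.15, gstar=0.5, mu1=2.3, sigma1_sq=1.0, phi=-0.3,
        sigma_tau_sq=0.5)
    return items, persons, structural


def make_state(data, items, persons, structural, cls=None, d=None):
    """McmcState assembled from explicit parameter containers."""
    n, t = data.n_learners, data.n_times
    return McmcState(
        cls=np.zeros((n, t), dtype=np.int64) if cls is None else np.asarray(cls),
        d=np.zeros((n, t), dtype=np.int8) if d is None else np.asarray(d, dtype=np.int8),
        theta=persons.theta.copy(), tau=persons.tau.copy(),
        s=items.s.copy(), g=items.g.copy(), gamma=items.gamma.copy(),
        a=items.a.copy(), lambda0=structural.lambda0,
        lambda1=structural.lambda1, lambda2=structural.lambda2,
        pi=structural.pi.copy(), omega=structural.omega,
        gstar=structural.gstar, mu1=structural.mu1,
        sigma1_sq=structural.sigma1_sq, phi=structural.phi,
        sigma_tau_sq=structural.sigma_tau_sq)


@pytest.fixture
def profiles_k4():
    return enumerate_profiles(4)
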
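import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

import seizhmm as sz

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def random_gmmhmm(Q: int, M: int, D: int, rng: np.random.Generator) -> sz.GmmHmmModel:
    """Valid random model with SPD covariances, for oracle tests."""
    a = rng.random((Q, Q)) + 0.1
    a /= a.sum(axis=1, keepdims=True)
    pi = rng.random(Q) + 0.1
    pi /= pi.sum()
    w = rng.random((Q, M)) + 0.1
    w /= w.sum(axis=1, keepdims=True)
    mu = rng.normal(size=(Q, M, D))
    sigma = np.empty((Q, M, D, D))
    for j in range(Q):
        for k in range(M):
            A = rng.normal(size=(D, D))
            sigma[j, k] = A @ A.T + np.eye(D)
    return sz.GmmHmmModel(a=a, pi=pi, w=w, mu=mu, sigma=sigma)


def brute_force_loglik(model: sz.GmmHmmModel, x: np.ndarray) -> float:
    """Exhaustive sum over all state paths (independent oracle, tiny T only)."""
    T = x.shape[0]
    total = 0.0
    for path in itertools.product(range(model.Q), repeat=T):
        p = model.pi[path[0]] * sz.emission_prob(x[0], model, path[0])
        for t in range(1, T):
            p *= model.a[path[t - 1], path[t]] * sz.emission_prob(x[t], model, path[t])
        total += p
    return math.log(total)


@pytest.fixture(scope="session")
def two_state_model() -> sz.GmmHmmModel:
    """Well-separated 2-state, single-Gaussian model used for recovery tests."""
    return sz.GmmHmmModel(
        a=[[0.9, 0.1], [0.2, 0.8]], pi=[0.5, 0.5], w=[[1.0], [1.0]],
        mu=np.array([[[0.0, 0.0]], [[3.0, 3.0]]]),
        sigma=np.tile(np.eye(2), (2, 1, 1, 1)))


@pytest.fixture(scope="session")
def three_state_m2_model() -> sz.GmmHmmModel:
    """3-state, 2-component generating model for topology-selection studies."""
    return sz.GmmHmmModel(
        a=[[0.90, 0.07, 0.03], [0.05, 0.90, 0.05], [0.03, 0.07, 0.90]],
        pi=[1 / 3, 1 / 3, 1 / 3],
        w=[[0.6, 0.4], [0.5, 0.5], [0.7, 0.3]],
        mu=np.array([[[0, 0], [2, 2]], [[8, 0], [10, 2]], [[0, 8], [2, 10]]], float),
        sigma=np.tile(np.eye(2) * 0.5, (3, 2, 1, 1)))


@pytest.fixture(scope="session")
def sle_event():
    """One synthetic five-stage seizure-like event with 7-D/14-D features."""
    sig, gt = sz.simulate_sle_lfp(sz.default_stage_recipe(), seed=42)
    pre = sz.preprocess(sig)
    f7 = sz.cwt_band_coefficients(pre)
    f14 = sz.append_rate_of_change(f7)
    return {"sig": sig, "pre": pre, "f7": f7, "f14": f14, "gt": gt}
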
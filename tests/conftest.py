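"""Shared fixtures and independent oracles.

Oracles here deliberately avoid the library code paths they check: the Poisson
tail is summed term by term from the pmf, and HMM likelihoods are brute-force
sums over every state path.
"""

import math

import numpy as np
import pytest

from chromdyn import SimulationConfig, simulate_dataset


# --------------------------------------------------------------------------- #
# independent oracles
# --------------------------------------------------------------------------- #

def exact_poisson_upper_tail(count: int, lam: float) -> float:
    """P(X >= count | lam) by direct pmf summation (log-space terms)."""
    if count <= 0:
        return 1.0
    # sum P(X = i) for i < count, then complement
    terms = [math.exp(-lam + i * math.log(lam) - math.lgamma(i + 1))
             for i in range(count)]
    return max(0.0, 1.0 - math.fsum(terms))


def brute_force_loglik(obs, pi, A, em, eps=1e-6):
    """HMM log-likelihood by enumerating all K^T state paths."""
    from itertools import product

    T, M = obs.shape
    K = len(pi)
    p = np.clip(em, eps, 1 - eps)
    total = 0.0
    for path in product(range(K), repeat=T):
        prob = pi[path[0]]
        for t in range(1, T):
            prob *= A[path[t - 1], path[t]]
        for t, k in enumerate(path):
            prob *= np.prod(np.where(obs[t] == 1, p[k], 1 - p[k]))
        total += prob
    return math.log(total)


def brute_force_posteriors(obs, pi, A, em, eps=1e-6):
    """Per-position state posteriors by path enumeration."""
    from itertools import product

    T, M = obs.shape
    K = len(pi)
    p = np.clip(em, eps, 1 - eps)
    gamma = np.zeros((T, K))
    for path in product(range(K), repeat=T):
        prob = pi[path[0]]
        for t in range(1, T):
            prob *= A[path[t - 1], path[t]]
        for t, k in enumerate(path):
            prob *= np.prod(np.where(obs[t] == 1, p[k], 1 - p[k]))
        for t, k in enumerate(path):
            gamma[t, k] += prob
    return gamma / gamma.sum(axis=1, keepdims=True)


def random_hmm_instance(K, T, M, rng):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    em = rng.uniform(0.05, 0.95, size=(K, M))
    obs = (rng.random((T, M)) < 0.5).astype(float)
    return obs, pi, A, em


def match_states(recovered: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Permutation mapping recovered state index -> truth state index that
    minimizes total L1 emission distance (Hungarian assignment)."""
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(recovered[:, None, :] - truth[None, :, :]).sum(axis=2)
    _, col = linear_sum_assignment(cost)
    return col


# --------------------------------------------------------------------------- #
# fixtures
# --------------------------------------------------------------------------- #

@pytest.fixture(scope="session")
def desk_config():
    """Small but non-trivial study design: 0.5 Mb, 2500 bins, 40 genes."""
    return SimulationConfig(
        chrom_sizes=(("chr1", 300_000), ("chr2", 200_000)),
        n_genes=40, seed=7,
    )


@pytest.fixture(scope="session")
def desk_dataset(desk_config):
    """(truth, mark_data, expression_data) for the desk-scale design."""
    return simulate_dataset(desk_config)
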
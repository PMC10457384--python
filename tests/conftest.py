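"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from scipy.stats import norm

import smkinetics as sk


@pytest.fixture
def binding_scheme():
    """Two-state encounter-intermediate/bound scheme, K_D = 205 nM."""
    return sk.build_binding_scheme(kd=205e-9, k_off=200.0)


@pytest.fixture
def apo_scheme():
    """Apo self-folding scheme (0 <-> 1 <-> 2 plus parallel 1* branch)."""
    return sk.build_apo_scheme()


def random_hmm(rng: np.random.Generator, n_states: int) -> sk.GaussianHMM:
    """Random valid Gaussian HMM with distinct descending means."""
    means = np.sort(rng.uniform(-2, 2, n_states))[::-1]
    means += np.arange(n_states)[::-1] * 0.05  # guarantee strict ordering
    sds = rng.uniform(0.2, 1.0, n_states)
    A = rng.uniform(0.1, 1.0, (n_states, n_states))
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.1, 1.0, n_states)
    pi /= pi.sum()
    return sk.GaussianHMM(pi, A, means, sds)


def _all_path_logprobs(x: np.ndarray, hmm: sk.GaussianHMM) -> tuple[np.ndarray, np.ndarray]:
    """Log-probability of every hidden path, enumerated exhaustively
    (lexicographic path order)."""
    T, n = len(x), hmm.n_states
    logB = norm.logpdf(x[:, None], hmm.means[None, :], hmm.sds[None, :])
    logA = np.log(hmm.transition_probs)
    paths = np.array(list(product(range(n), repeat=T)))
    lp = np.log(hmm.initial_probs)[paths[:, 0]] + logB[0, paths[:, 0]]
    for t in range(1, T):
        lp += logA[paths[:, t - 1], paths[:, t]] + logB[t, paths[:, t]]
    return paths, lp


def brute_force_loglik(x: np.ndarray, hmm: sk.GaussianHMM) -> float:
    """Exhaustive sum over all hidden paths (oracle for the forward pass)."""
    from scipy.special import logsumexp

    _, lp = _all_path_logprobs(x, hmm)
    return float(logsumexp(lp))


def brute_force_viterbi(x: np.ndarray, hmm: sk.GaussianHMM) -> np.ndarray:
    """Exhaustive argmax over all hidden paths; ties to the lexicographically
    smallest (lowest-index) path (argmax returns the first maximum)."""
    paths, lp = _all_path_logprobs(x, hmm)
    return paths[int(np.argmax(lp))]


def two_state_scheme(k01: float, k10: float, levels=(1.0, 0.9)) -> sk.KineticScheme:
    """Plain two-state scheme with the given exit rates."""
    states = [sk.KineticState("up", levels[0]), sk.KineticState("down", levels[1])]
    return sk.KineticScheme.from_rates(states, {(0, 1): k01, (1, 0): k10})
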
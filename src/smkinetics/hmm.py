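"""Gaussian-emission hidden Markov model idealization of current traces.

This is the package's trace idealizer: Baum-Welch EM fitting, stable
forward/backward with per-frame scaling (log-likelihood accumulated in the
log domain), Viterbi decoding, BIC-based state-count selection, and a
half-amplitude threshold idealizer kept as an independent baseline.

States are always labelled by descending emission mean, so state 0 is the
highest-current (least folded) level, matching the 0/1/2 convention of
multi-state conductance traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class GaussianHMM:
    """Per-sample HMM with Gaussian emissions.

    means are strictly sorted descending (state 0 = highest current);
    probability rows sum to one; sds > 0.
    """

    initial_probs: np.ndarray
    transition_probs: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float | None = None
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self):
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        n = len(self.means)
        if self.initial_probs.shape != (n,) or self.transition_probs.shape != (n, n):
            raise ValueError("inconsistent HMM dimensions")
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be > 0")
        if abs(self.initial_probs.sum() - 1.0) > 1e-12 or np.any(
            np.abs(self.transition_probs.sum(axis=1) - 1.0) > 1e-12
        ):
            raise ValueError("probability rows must sum to 1")
        if np.any((self.initial_probs < 0) | (self.initial_probs > 1)) or np.any(
            (self.transition_probs < 0) | (self.transition_probs > 1)
        ):
            raise ValueError("probabilities must lie in [0, 1]")
        if n > 1 and not np.all(np.diff(self.means) < 0):
            raise ValueError("means must be strictly sorted descending")

    @property
    def n_states(self) -> int:
        return len(self.means)


@dataclass
class IdealizedTrace:
    """Per-sample state labels plus the model that produced them."""

    labels: np.ndarray
    loglik: float | None
    hmm: GaussianHMM | None
    sampling_rate: float
    means: np.ndarray = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.means is None and self.hmm is not None:
            self.means = self.hmm.means
        self.means = np.asarray(self.means, dtype=float)

    def __len__(self) -> int:
        return len(self.labels)


def _samples(trace) -> np.ndarray:
    x = trace.samples if hasattr(trace, "samples") else trace
    return np.ascontiguousarray(x, dtype=np.float64)


def _frame_logprob(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return -0.5 * z * z - np.log(sds)[None, :] - 0.5 * _LOG2PI


@njit(cache=True)
def _forward(logB, A, pi):
    T, n = logB.shape
    alpha = np.empty(n)
    tmp = np.empty(n)
    ll = 0.0
    m = logB[0].max()
    c = 0.0
    for i in range(n):
        alpha[i] = pi[i] * math.exp(logB[0, i] - m)
        c += alpha[i]
    ll += math.log(c) + m
    for i in range(n):
        alpha[i] /= c
    for t in range(1, T):
        m = logB[t].max()
        c = 0.0
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += alpha[j] * A[j, i]
            tmp[i] = s * math.exp(logB[t, i] - m)
            c += tmp[i]
        ll += math.log(c) + m
        for i in range(n):
            alpha[i] = tmp[i] / c
    return ll


@njit(cache=True)
def _forward_backward(logB, A, pi):
    """Scaled forward-backward. Returns (loglik, gamma[T,n], xi_sum[n,n])."""
    T, n = logB.shape
    alpha = np.empty((T, n))
    c = np.empty(T)
    m = np.empty(T)
    ll = 0.0
    for t in range(T):
        mt = logB[t, 0]
        for i in range(1, n):
            if logB[t, i] > mt:
                mt = logB[t, i]
        m[t] = mt
    ct = 0.0
    for i in range(n):
        alpha[0, i] = pi[i] * math.exp(logB[0, i] - m[0])
        ct += alpha[0, i]
    c[0] = ct
    ll += math.log(ct) + m[0]
    for i in range(n):
        alpha[0, i] /= ct
    for t in range(1, T):
        ct = 0.0
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += alpha[t - 1, j] * A[j, i]
            alpha[t, i] = s * math.exp(logB[t, i] - m[t])
            ct += alpha[t, i]
        c[t] = ct
        ll += math.log(ct) + m[t]
        for i in range(n):
            alpha[t, i] /= ct
    gamma = np.empty((T, n))
    xi_sum = np.zeros((n, n))
    beta = np.ones(n)
    beta_new = np.empty(n)
    for i in range(n):
        gamma[T - 1, i] = alpha[T - 1, i]
    for t in range(T - 2, -1, -1):
        bb = np.empty(n)
        for j in range(n):
            bb[j] = math.exp(logB[t + 1, j] - m[t + 1]) * beta[j] / c[t + 1]
        for i in range(n):
            s = 0.0
            for j in range(n):
                v = alpha[t, i] * A[i, j] * bb[j]
                xi_sum[i, j] += v
                s += A[i, j] * bb[j]
            beta_new[i] = s
            gamma[t, i] = alpha[t, i] * s
        tot = 0.0
        for i in range(n):
            tot += gamma[t, i]
        for i in range(n):
            gamma[t, i] /= tot
            beta[i] = beta_new[i]
    return ll, gamma, xi_sum


@njit(cache=True)
def _viterbi(logB, logA, logpi):
    """Log-space Viterbi; ties broken toward the lower state index."""
    T, n = logB.shape
    delta = np.empty((T, n))
    back = np.empty((T, n), dtype=np.int32)
    for i in range(n):
        delta[0, i] = logpi[i] + logB[0, i]
        back[0, i] = 0
    for t in range(1, T):
        for i in range(n):
            best = delta[t - 1, 0] + logA[0, i]
            arg = 0
            for j in range(1, n):
                v = delta[t - 1, j] + logA[j, i]
                if v > best:
                    best = v
                    arg = j
            delta[t, i] = best + logB[t, i]
            back[t, i] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for i in range(1, n):
        if delta[T - 1, i] > best:
            best = delta[T - 1, i]
            arg = i
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def loglik(trace, hmm: GaussianHMM) -> float:
    """Forward-algorithm log-likelihood (nats) of the samples under the HMM."""
    x = _samples(trace)
    logB = _frame_logprob(x, hmm.means, hmm.sds)
    return float(_forward(logB, hmm.transition_probs, hmm.initial_probs))


def viterbi(trace, hmm: GaussianHMM, sampling_rate: float | None = None) -> IdealizedTrace:
    """Maximum a posteriori state path; ties go to the lower state index."""
    x = _samples(trace)
    logB = _frame_logprob(x, hmm.means, hmm.sds)
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.transition_probs)
        logpi = np.log(hmm.initial_probs)
    labels = _viterbi(logB, logA, logpi)
    ll = float(_forward(logB, hmm.transition_probs, hmm.initial_probs))
    fs = sampling_rate if sampling_rate is not None else getattr(trace, "sampling_rate", 1.0)
    return IdealizedTrace(labels=labels, loglik=ll, hmm=hmm, sampling_rate=fs)


def _sort_descending(pi, A, means, sds):
    order = np.argsort(-means, kind="stable")
    return pi[order], A[np.ix_(order, order)], means[order], sds[order]


def _init_params(x: np.ndarray, n_states: int, rng: np.random.Generator | None = None):
    q = (np.arange(n_states) + 0.5) / n_states
    means = np.quantile(x, q)
    if rng is not None:  # jittered restart
        means = means + rng.normal(0.0, x.std() / (4 * n_states), n_states)
    # strictly increasing guard for degenerate quantiles
    eps = max(x.std(), 1e-12) * 1e-6
    for i in range(1, n_states):
        if means[i] <= means[i - 1]:
            means[i] = means[i - 1] + eps
    sds = np.full(n_states, x.std() / math.sqrt(n_states))
    sds = np.maximum(sds, 1e-12)
    A = np.full((n_states, n_states), 0.01 / max(n_states - 1, 1))
    np.fill_diagonal(A, 0.99)
    if n_states == 1:
        A = np.ones((1, 1))
    pi = np.full(n_states, 1.0 / n_states)
    return pi, A, means, sds


def fit_hmm(
    trace,
    n_states: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed=None,
) -> GaussianHMM:
    """Baum-Welch EM fit of an ``n_states`` Gaussian HMM to the trace.

    Initialization: emission means at evenly spaced quantiles, SDs at the
    pooled SD / sqrt(n_states), near-diagonal transitions. Convergence when
    the per-sample log-likelihood gain drops below ``tol`` (nats/sample).
    Variance collapse triggers up to 3 re-seeded restarts, then an error.
    States are relabelled by descending mean.
    """
    x = _samples(trace)
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if len(x) < 10 * n_states:
        raise ValueError(f"trace length {len(x)} < 10 * n_states")
    if n_states == 1:
        mu = float(x.mean())
        sd = float(x.std())
        ll = float(np.sum(-0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * _LOG2PI))
        return GaussianHMM(np.ones(1), np.ones((1, 1)), np.array([mu]), np.array([sd]), loglik=ll)

    rng = np.random.default_rng(seed)
    var_floor = 1e-12 * x.var()
    T = len(x)
    for attempt in range(3):
        pi, A, means, sds = _init_params(x, n_states, rng if attempt else None)
        prev_ll = -np.inf
        collapsed = False
        ll = prev_ll
        for it in range(1, max_iter + 1):
            logB = _frame_logprob(x, means, sds)
            ll, gamma, xi_sum = _forward_backward(logB, A, pi)
            if ll < prev_ll - 1e-9 * max(1.0, abs(prev_ll)):
                warnings.warn(f"EM log-likelihood decreased at iteration {it}")
            # M-step
            pi = gamma[0] / gamma[0].sum()
            rowsum = xi_sum.sum(axis=1, keepdims=True)
            A = np.where(rowsum > 0, xi_sum / np.where(rowsum > 0, rowsum, 1.0), 1.0 / n_states)
            w = gamma.sum(axis=0)
            means = gamma.T @ x / w
            var = np.einsum("ti,ti->i", gamma, (x[:, None] - means[None, :]) ** 2) / w
            if np.any(var < var_floor):
                collapsed = True
                break
            sds = np.sqrt(var)
            if ll - prev_ll < tol * T and it > 1:
                prev_ll = ll
                break
            prev_ll = ll
        if not collapsed:
            pi, A, means, sds = _sort_descending(pi, A, means, sds)
            # guard against exactly tied means after sorting
            for i in range(1, n_states):
                if means[i] >= means[i - 1]:
                    means[i] = means[i - 1] - 1e-12
            return GaussianHMM(
                pi, A, means, sds, loglik=float(ll), n_iter=it,
                converged=ll - prev_ll < tol * T or it < max_iter,
            )
        warnings.warn(f"emission variance collapse; restart {attempt + 1}/3")
    raise RuntimeError("EM failed: emission variance collapsed in 3 restarts")


def select_n_states(trace, candidates=range(1, 7), seed=None) -> tuple[int, dict[int, float]]:
    """Choose the state count by BIC over ``candidates``.

    BIC = -2 loglik + p ln(T) with p = n^2 + 2n - 1 free parameters
    (transitions, emissions, initial distribution). EM failures skip the
    candidate with a warning.
    """
    x = _samples(trace)
    T = len(x)
    bics: dict[int, float] = {}
    for n in candidates:
        if not 1 <= n <= 6:
            raise ValueError("candidate state counts must lie in [1, 6]")
        try:
            hmm = fit_hmm(x, n, seed=seed)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"EM failed for n_states={n}: {exc}")
            continue
        p = n * n + 2 * n - 1
        bics[n] = -2.0 * hmm.loglik + p * math.log(T)
    if not bics:
        raise RuntimeError("EM failed for every candidate state count")
    best = min(bics, key=lambda n: (bics[n], n))
    return best, bics


def threshold_idealize(trace, levels, sampling_rate: float | None = None) -> IdealizedTrace:
    """Half-amplitude baseline idealizer: nearest level by midpoint thresholds.

    Samples exactly on a midpoint are assigned to the higher-current state.
    """
    levels = np.sort(np.asarray(levels, dtype=float))[::-1]
    if len(levels) < 2:
        raise ValueError("at least 2 levels required")
    x = _samples(trace)
    mids = (levels[:-1] + levels[1:]) / 2.0  # decreasing
    labels = (x[:, None] < mids[None, :]).sum(axis=1).astype(np.int64)
    fs = sampling_rate if sampling_rate is not None else getattr(trace, "sampling_rate", 1.0)
    return IdealizedTrace(labels=labels, loglik=None, hmm=None, sampling_rate=fs, means=levels)
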
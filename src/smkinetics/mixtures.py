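"""Exponential-mixture maximum likelihood for dwell-time distributions.

Dwells of a memoryless state are exponential; a state that hides several
kinetic sub-populations (same current level, different exit rates) shows a
mixture of exponentials.  Fits are unbinned MLE under left truncation at
the idealization dead time: each observed dwell ``x >= t0`` has density
``sum_j w_j * (1/tau_j) * exp(-(x - t0)/tau_j)``, which corrects the
mean-dwell bias introduced by discarding events shorter than ``t0``
(adequate for taus of at least ~3x the dead time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp


@dataclass
class DwellFit:
    """Exponential-mixture fit of one state's dwell durations.

    components are ``(tau_seconds, weight)`` sorted by tau ascending; weights
    are post-truncation mixing proportions and sum to one.
    """

    components: list[tuple[float, float]]
    loglik: float
    n_dwells: int
    dead_time: float = 0.0
    state: int | None = None
    tau_ci: list[tuple[float, float]] = field(default_factory=list)
    weight_ci: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        taus = [t for t, _ in self.components]
        weights = [w for _, w in self.components]
        if any(t <= 0 for t in taus) or any(w <= 0 for w in weights):
            raise ValueError("taus and weights must be > 0")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if taus != sorted(taus):
            raise ValueError("components must be sorted by tau ascending")

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for t, _ in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components])


@dataclass
class RateEstimate:
    """A rate constant ``k = 1/tau`` with its provenance and condition."""

    k: float
    k_ci: tuple[float, float]
    source: tuple[int | None, int]
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("rate must be > 0")


def _mixture_loglik(y: np.ndarray, taus: np.ndarray, weights: np.ndarray) -> float:
    logp = np.log(weights)[None, :] - np.log(taus)[None, :] - y[:, None] / taus[None, :]
    return float(logsumexp(logp, axis=1).sum())


def _em_fit(y: np.ndarray, k: int, max_iter: int = 2000, tol: float = 1e-10):
    n = len(y)
    # deterministic init: taus at spread quantiles of the shifted durations
    q = (np.arange(k) + 1.0) / (k + 1.0)
    taus = np.maximum(np.quantile(y, q), y.mean() * 1e-3)
    for i in range(1, k):  # enforce distinct
        if taus[i] <= taus[i - 1]:
            taus[i] = taus[i - 1] * 1.5
    weights = np.full(k, 1.0 / k)
    prev = -np.inf
    for _ in range(max_iter):
        logr = np.log(weights)[None, :] - np.log(taus)[None, :] - y[:, None] / taus[None, :]
        norm = logsumexp(logr, axis=1, keepdims=True)
        r = np.exp(logr - norm)
        ll = float(norm.sum())
        w = r.sum(axis=0)
        weights = w / n
        taus = (r * y[:, None]).sum(axis=0) / np.maximum(w, 1e-300)
        taus = np.maximum(taus, 1e-300)
        if ll - prev < tol * n:
            prev = ll
            break
        prev = ll
    return taus, weights, prev


def fit_exponential_mixture(
    durations,
    n_components: int = 1,
    dead_time: float = 0.0,
    seed=None,
    n_boot: int = 0,
    state: int | None = None,
) -> DwellFit:
    """Left-truncated exponential-mixture MLE of dwell durations (seconds).

    ``n_components=1`` uses the closed form ``tau = mean(x - dead_time)``.
    Bootstrap percentile CIs (``n_boot`` resamples, seeded) are attached
    when requested.
    """
    x = np.asarray(durations, dtype=float)
    x = x[x > dead_time]
    if len(x) < 10:
        raise ValueError(f"need >= 10 uncensored dwells beyond the dead time, got {len(x)}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > len(x) / 10:
        raise ValueError(f"n_components={n_components} too large for {len(x)} dwells")
    y = x - dead_time

    def _fit(yv):
        if n_components == 1:
            tau = float(yv.mean())
            ll = _mixture_loglik(yv, np.array([tau]), np.array([1.0]))
            return np.array([tau]), np.array([1.0]), ll
        return _em_fit(yv, n_components)

    taus, weights, ll = _fit(y)
    order = np.argsort(taus)
    taus, weights = taus[order], weights[order]
    if np.any(weights < 1e-4):
        warnings.warn("degenerate mixture component (weight < 1e-4)")
        weights = np.maximum(weights, 1e-12)
        weights /= weights.sum()

    tau_ci: list[tuple[float, float]] = []
    weight_ci: list[tuple[float, float]] = []
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot_taus = np.empty((n_boot, n_components))
        boot_w = np.empty((n_boot, n_components))
        for b in range(n_boot):
            yb = rng.choice(y, size=len(y), replace=True)
            tb, wb, _ = _fit(yb)
            ob = np.argsort(tb)
            boot_taus[b] = tb[ob]
            boot_w[b] = wb[ob]
        for j in range(n_components):
            tau_ci.append(tuple(np.percentile(boot_taus[:, j], [2.5, 97.5])))
            weight_ci.append(tuple(np.percentile(boot_w[:, j], [2.5, 97.5])))

    return DwellFit(
        components=[(float(t), float(w)) for t, w in zip(taus, weights)],
        loglik=float(ll),
        n_dwells=len(x),
        dead_time=dead_time,
        state=state,
        tau_ci=tau_ci,
        weight_ci=weight_ci,
    )


def choose_components(
    durations,
    max_components: int = 3,
    dead_time: float = 0.0,
    seed=None,
) -> tuple[int, dict[int, float]]:
    """Minimum-BIC exponential-mixture component count.

    BIC = -2 loglik + (2k - 1) ln(n) for a k-component mixture.
    """
    x = np.asarray(durations, dtype=float)
    x = x[x > dead_time]
    n = len(x)
    bics: dict[int, float] = {}
    for k in range(1, max_components + 1):
        if k > n / 10:
            break
        fit = fit_exponential_mixture(x, k, dead_time=dead_time, seed=seed)
        bics[k] = -2.0 * fit.loglik + (2 * k - 1) * np.log(n)
    best = min(bics, key=lambda k: (bics[k], k))
    return best, bics


def rate_constants(fit: DwellFit, condition: dict | None = None) -> list[RateEstimate]:
    """Rate constants ``k = 1/tau`` per mixture component, CIs propagated
    from the bootstrap tau CIs (largest k first would invert the tau order,
    so component order is preserved: smallest tau -> largest k)."""
    out = []
    for j, (tau, _w) in enumerate(fit.components):
        if fit.tau_ci:
            lo, hi = fit.tau_ci[j]
            ci = (1.0 / hi, 1.0 / lo)
        else:
            ci = (np.nan, np.nan)
        out.append(RateEstimate(k=1.0 / tau, k_ci=ci, source=(fit.state, j), condition=dict(condition or {})))
    return out
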
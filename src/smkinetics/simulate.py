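"""Exact continuous-time Markov-chain (Gillespie) simulation of state paths.

Supports optional slow modulation of the rate matrix (dynamic disorder):
either a deterministic two-regime alternation or a lognormal
Ornstein-Uhlenbeck factor, both much slower than the dwell timescale.  The
modulation multiplies every rate by a common factor, so stationary occupancy
is untouched while dwell times stretch and shrink coherently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .schemes import KineticScheme, stationary_distribution


@dataclass
class RateModulation:
    """Slow rate modulation producing dynamic disorder.

    mode:
        ``"none"`` | ``"two_regime"`` | ``"lognormal_ou"``.
    timescale:
        Regime length / OU correlation time, s. Should be much longer than
        the mean dwell (warned otherwise).
    amplitude:
        Fold-change of the mean dwell between slow/fast regimes
        (two_regime) or between +/-1 sd of the OU factor (lognormal_ou).
    """

    mode: str = "none"
    timescale: float = 10.0
    amplitude: float = 1.0

    def __post_init__(self):
        if self.mode not in ("none", "two_regime", "lognormal_ou"):
            raise ValueError(f"unknown modulation mode {self.mode!r}")
        if self.mode != "none" and (self.timescale <= 0 or self.amplitude <= 0):
            raise ValueError("timescale and amplitude must be > 0")


@dataclass
class StatePath:
    """Ground-truth piecewise-constant state trajectory.

    ``states[k]`` is occupied on ``[start_times[k], start_times[k] +
    durations[k])``; dwells are contiguous and cover ``[0, total_duration]``.
    """

    states: np.ndarray
    durations: np.ndarray
    total_duration: float

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        self.durations = np.asarray(self.durations, dtype=float)
        if len(self.states) != len(self.durations):
            raise ValueError("states and durations must have equal length")
        if np.any(self.durations <= 0):
            raise ValueError("every dwell duration must be > 0")
        if not np.isclose(self.durations.sum(), self.total_duration, rtol=1e-9, atol=1e-12):
            raise ValueError("dwell durations must cover [0, total_duration]")

    @property
    def n_events(self) -> int:
        return len(self.states)

    @property
    def start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.durations)[:-1]])

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.durations)])

    def events(self):
        """Iterate ``(state, entry_time, exit_time)``."""
        t0 = 0.0
        for s, d in zip(self.states, self.durations):
            yield int(s), t0, t0 + d
            t0 += d

    def labels_at(self, times: np.ndarray) -> np.ndarray:
        """State index occupied at each of the given times."""
        idx = np.searchsorted(self.boundaries, times, side="right") - 1
        return self.states[np.clip(idx, 0, self.n_events - 1)]


def _modulation_profile(modulation: RateModulation, duration: float, rng: np.random.Generator):
    """Piecewise-constant factor profile: (boundary times incl. 0/duration, factors)."""
    if modulation.timescale >= duration:
        warnings.warn("modulation timescale exceeds path duration; factor is constant")
    if modulation.mode == "two_regime":
        # rates alternate sqrt(amp) and 1/sqrt(amp): mean-dwell fold-change = amplitude
        edges = np.arange(0.0, duration, modulation.timescale)
        factors = np.where(np.arange(len(edges)) % 2 == 0, np.sqrt(modulation.amplitude), 1.0 / np.sqrt(modulation.amplitude))
    else:  # lognormal_ou
        dt = modulation.timescale / 5.0
        edges = np.arange(0.0, duration, dt)
        sigma = np.log(modulation.amplitude) / 2.0
        rho = np.exp(-dt / modulation.timescale)
        x = np.empty(len(edges))
        x[0] = sigma * rng.standard_normal()
        innov = sigma * np.sqrt(1 - rho**2) * rng.standard_normal(len(edges) - 1)
        for k in range(1, len(edges)):
            x[k] = rho * x[k - 1] + innov[k - 1]
        factors = np.exp(x)
    return np.append(edges, duration), factors


def _dwell_with_modulation(t: float, rate: float, edges, factors, target: float) -> float:
    """Time to accumulate hazard ``target`` starting at ``t`` with piecewise factor."""
    seg = int(np.searchsorted(edges, t, side="right") - 1)
    seg = min(max(seg, 0), len(factors) - 1)
    elapsed = 0.0
    remaining = target
    while True:
        seg_end = edges[seg + 1] if seg + 1 < len(edges) else np.inf
        r = rate * factors[seg]
        width = seg_end - (t + elapsed)
        if r * width >= remaining or seg + 1 >= len(factors):
            return elapsed + remaining / r
        remaining -= r * width
        elapsed += width
        seg += 1


def simulate_path(
    scheme: KineticScheme,
    duration: float,
    T: float | None = None,
    concentrations: dict[str, float] | None = None,
    seed=None,
    modulation: RateModulation | None = None,
    start: int | str | None = None,
) -> StatePath:
    """Sample an exact CTMC trajectory of the scheme over ``[0, duration]``.

    Dwell in state i is exponential with the total exit rate; the successor
    is chosen proportionally to ``Q[i, j]``.  Entering an absorbing state
    ends the path there, with the remaining time as the final dwell.
    Bit-reproducible given ``seed``.

    ``start``: initial state index or name; default samples from the
    stationary distribution (falls back to state 0 for reducible chains).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = scheme.effective_rate_matrix(T=T, concentrations=concentrations)
    if not np.all(np.isfinite(Q)):
        raise ValueError("effective rates must be finite")
    n = Q.shape[0]
    exit_rates = -np.diag(Q)
    probs = np.zeros_like(Q)
    for i in range(n):
        if exit_rates[i] > 0:
            probs[i] = Q[i] / exit_rates[i]
            probs[i, i] = 0.0
    cum = np.cumsum(probs, axis=1)

    if start is None:
        try:
            pi = stationary_distribution(scheme, T=T, concentrations=concentrations)
        except ValueError:
            pi = np.zeros(n)
            pi[0] = 1.0
        state = int(np.searchsorted(np.cumsum(pi), rng.random()))
        state = min(state, n - 1)
    elif isinstance(start, str):
        state = scheme.state_index(start)
    else:
        state = int(start)

    mod_edges = mod_factors = None
    if modulation is not None and modulation.mode != "none":
        mean_dwell = 1.0 / exit_rates[exit_rates > 0].max() if np.any(exit_rates > 0) else np.inf
        if modulation.timescale < 10 * mean_dwell:
            warnings.warn("modulation timescale is not much longer than the mean dwell")
        mod_edges, mod_factors = _modulation_profile(modulation, duration, rng)

    states: list[int] = []
    durations: list[float] = []
    t = 0.0
    while t < duration:
        q = exit_rates[state]
        if q <= 0:  # absorbing: remaining time is the final dwell
            states.append(state)
            durations.append(duration - t)
            break
        target = rng.exponential(1.0)
        if mod_edges is None:
            dwell = target / q
        else:
            dwell = _dwell_with_modulation(t, q, mod_edges, mod_factors, target)
        if t + dwell >= duration:
            states.append(state)
            durations.append(duration - t)
            break
        states.append(state)
        durations.append(dwell)
        t += dwell
        state = int(np.searchsorted(cum[state], rng.random() * cum[state, -1], side="right"))
        state = min(state, n - 1)
    return StatePath(np.array(states), np.array(durations), duration)
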
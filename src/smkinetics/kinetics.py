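"""Higher-level kinetic statistics: dynamic disorder and observed binding
rates (k_obs) versus ligand concentration.

Dynamic disorder is detected as excess spread of windowed (per-second)
arithmetic mean dwell times relative to the 1/sqrt(m) statistical floor of a
homogeneous memoryless process.  k_obs counts entries into the bound state
per second of observation; its concentration dependence discriminates
induced-fit (hyperbolically increasing) binding from conformational
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .hmm import IdealizedTrace
from .simulate import StatePath


@dataclass
class DynamicDisorderResult:
    """Windowed mean-dwell summary for one state."""

    window: float
    window_means: np.ndarray
    cv: float
    iqr: tuple[float, float]
    n_windows: int

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.cv < 0:
            raise ValueError("CV must be >= 0")


@dataclass
class KObsCurve:
    """Bound-state entry rate per second of observation, by concentration."""

    concentrations: np.ndarray
    k_obs: np.ndarray
    n_entries: np.ndarray | None = None
    total_time: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.k_obs < 0):
            raise ValueError("k_obs must be >= 0")


@dataclass
class InducedFitFit:
    """Hyperbolic observed-rate fit ``k_obs(C) = k_r + k_f * C / (K_1 + C)``."""

    k_f: float
    k_r: float
    K_1: float
    k_f_ci: tuple[float, float]
    k_r_ci: tuple[float, float]
    K_1_ci: tuple[float, float]
    non_identifiable: bool = False

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return self.k_r + self.k_f * c / (self.K_1 + c)


def dynamic_disorder(dwell_table: pd.DataFrame, state: int, window: float = 1.0) -> DynamicDisorderResult:
    """Per-window arithmetic mean dwell of ``state`` and its coefficient of
    variation across windows (dwells binned by entry time; empty windows
    skipped)."""
    if window <= 0:
        raise ValueError("window must be > 0")
    span = float((dwell_table["start_s"] + dwell_table["duration_s"]).max())
    if span < 10 * window:
        raise ValueError(f"total observation {span:.3g} s < 10 windows of {window} s")
    sel = dwell_table[(dwell_table["state"] == state) & (~dwell_table["censored"])]
    if sel.empty:
        raise ValueError(f"no uncensored dwells of state {state}")
    bins = np.floor(sel["start_s"].to_numpy() / window).astype(int)
    means = sel.groupby(bins)["duration_s"].mean().to_numpy()
    if len(means) < 3:
        raise ValueError(f"only {len(means)} non-empty windows; need >= 3")
    cv = float(means.std(ddof=1) / means.mean())
    iqr = tuple(np.percentile(means, [25, 75]))
    return DynamicDisorderResult(window=window, window_means=means, cv=cv, iqr=iqr, n_windows=len(means))


def _entries_and_time(obj, bound_state: int) -> tuple[int, float]:
    if isinstance(obj, StatePath):
        s = obj.states
        entries = int(np.sum((s[1:] == bound_state) & (s[:-1] != bound_state)))
        if len(s) and s[0] == bound_state:
            pass  # starting inside the bound state is not an entry
        return entries, float(obj.total_duration)
    labels = np.asarray(obj.labels)
    entries = int(np.sum((labels[1:] == bound_state) & (labels[:-1] != bound_state)))
    return entries, len(labels) / obj.sampling_rate


def compute_kobs(traces_by_conc: dict[float, list], bound_state: int) -> KObsCurve:
    """k_obs per concentration: entries into the bound state divided by the
    total observation time.  Accepts idealized traces or ground-truth paths."""
    concs = sorted(traces_by_conc)
    kobs, counts, times = [], [], []
    for c in concs:
        n_entries = 0
        total = 0.0
        for obj in traces_by_conc[c]:
            e, t = _entries_and_time(obj, bound_state)
            n_entries += e
            total += t
        if total <= 0:
            raise ValueError(f"zero observation time at concentration {c}")
        kobs.append(n_entries / total)
        counts.append(n_entries)
        times.append(total)
    return KObsCurve(np.array(concs), np.array(kobs), np.array(counts), np.array(times))


def fit_induced_fit(curve: KObsCurve, weights=None) -> InducedFitFit:
    """Weighted least-squares fit of the two-step induced-fit observed rate
    ``k_obs(C) = k_r + k_f * C / (K_1 + C)``.

    A flat curve is flagged non-identifiable (the k_f CI spans 0).
    """
    c = curve.concentrations
    k = curve.k_obs
    if len(c) < 4:
        raise ValueError("need >= 4 concentrations")
    sigma = None
    if weights is not None:
        sigma = 1.0 / np.sqrt(np.asarray(weights, dtype=float))

    def f(C, k_f, k_r, K_1):
        return k_r + k_f * C / (K_1 + C)

    span = float(k.max() - k.min())
    p0 = [max(span, 1e-12), max(float(k.min()), 0.0), float(np.median(c))]
    popt, pcov = curve_fit(
        f, c, k, p0=p0,
        bounds=([0.0, 0.0, 1e-30], [np.inf, np.inf, np.inf]),
        sigma=sigma, absolute_sigma=sigma is not None,
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000, x_scale="jac",
    )
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    cis = [(p - 1.96 * s, p + 1.96 * s) for p, s in zip(popt, se)]
    non_id = cis[0][0] <= 0.0 or not np.isfinite(se[0])
    return InducedFitFit(
        k_f=float(popt[0]), k_r=float(popt[1]), K_1=float(popt[2]),
        k_f_ci=tuple(cis[0]), k_r_ci=tuple(cis[1]), K_1_ci=tuple(cis[2]),
        non_identifiable=bool(non_id),
    )
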
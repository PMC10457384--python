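"""Binding and thermodynamic parameter estimation.

Bound-state populations from idealized traces, Hill dose-response fits
(dissociation constant K_D and cooperativity n), Arrhenius activation
energies from rate constants versus temperature, van't Hoff enthalpy /
entropy from equilibrium constants versus temperature (fitted in the
dissociation orientation), and apparent K_D under a fixed competing
inhibitor.

All temperatures are Kelvin internally; equilibrium constants follow the
dissociation convention ``K_diss = k_diss / k_bind = tau_unbound /
tau_bound``, so a positive fitted dH means dissociation is endothermic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .units import R


@dataclass
class BoundFraction:
    """Time fraction spent in the bound state, with a binomial-style CI."""

    alpha: float
    ci: tuple[float, float]
    n_samples: int


@dataclass
class DoseResponse:
    """Bound-state population versus ligand concentration."""

    concentrations: np.ndarray
    alpha_bind: np.ndarray
    alpha_se: np.ndarray | None = None
    n_traces: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.alpha_bind = np.asarray(self.alpha_bind, dtype=float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any((self.alpha_bind < 0) | (self.alpha_bind > 1)):
            raise ValueError("alpha_bind must lie in [0, 1]")
        if self.alpha_se is not None:
            self.alpha_se = np.asarray(self.alpha_se, dtype=float)


@dataclass
class HillFit:
    """Hill-equation fit: alpha(C) = C^n / (K_D^n + C^n)."""

    kd: float
    n_hill: float
    kd_ci: tuple[float, float]
    n_ci: tuple[float, float]
    residual: float
    apparent: bool = False
    inhibitor_conc: float | None = None

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return 1.0 / (1.0 + (self.kd / c) ** self.n_hill)


@dataclass
class ArrheniusFit:
    """ln k vs 1/T line: Ea = -slope * R, lnA = intercept."""

    Ea: float
    lnA: float
    r_squared: float
    Ea_ci: tuple[float, float]
    lnA_ci: tuple[float, float]

    def predict(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return np.exp(self.lnA - self.Ea / (R * T))


@dataclass
class VantHoffFit:
    """ln K vs 1/T line in the dissociation orientation:
    dH = -slope * R, dS = intercept * R."""

    dH: float
    dS: float
    r_squared: float
    dH_ci: tuple[float, float]
    dS_ci: tuple[float, float]
    orientation: str = "dissociation"

    def predict_lnK(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return -self.dH / (R * T) + self.dS / R

    def delta_g(self, T) -> np.ndarray:
        """Gibbs energy dG(T) = dH - T*dS; equals -R*T*ln K_pred(T)."""
        T = np.asarray(T, dtype=float)
        return self.dH - T * self.dS


@dataclass
class EquilibriumConstant:
    """Dissociation-direction equilibrium constant at one temperature."""

    K_diss: float
    temperature: float

    def __post_init__(self):
        if self.K_diss <= 0:
            raise ValueError("K_diss must be > 0")


def bound_fraction(idealized_traces, bound_state: int) -> BoundFraction:
    """Pooled time fraction of samples labelled as the bound state, with a
    Wilson score interval on the sample counts."""
    if not isinstance(idealized_traces, (list, tuple)):
        idealized_traces = [idealized_traces]
    hits = 0
    total = 0
    for it in idealized_traces:
        labels = np.asarray(it.labels)
        hits += int(np.sum(labels == bound_state))
        total += len(labels)
    if total == 0:
        raise ValueError("no samples")
    alpha = hits / total
    z = 1.96
    denom = 1 + z**2 / total
    centre = (alpha + z**2 / (2 * total)) / denom
    half = z * math.sqrt(alpha * (1 - alpha) / total + z**2 / (4 * total**2)) / denom
    return BoundFraction(alpha=alpha, ci=(centre - half, centre + half), n_samples=total)


def fit_hill(dr: DoseResponse) -> HillFit:
    """Least-squares Hill fit of a dose response.

    Fits ``(log10 K_D, n)`` with n bounded to [0.2, 4]; inverse-variance
    weights are used when per-point standard errors are available.
    """
    c = dr.concentrations
    a = dr.alpha_bind
    if len(c) < 4:
        raise ValueError("need >= 4 concentrations")
    if c.max() / c.min() < 10:
        raise ValueError("concentrations must span at least a 10x range")
    if np.all(a == 0) or np.all(a == 1):
        raise ValueError("dose response is flat at 0 or 1; K_D not identifiable")

    def f(C, log10_kd, n):
        kd = 10.0**log10_kd
        return 1.0 / (1.0 + (kd / C) ** n)

    # initial K_D: geometric interpolation to alpha = 0.5
    order = np.argsort(a)
    kd0 = float(np.interp(0.5, a[order], c[order], left=c.min(), right=c.max()))
    sigma = None
    if dr.alpha_se is not None:
        sigma = np.maximum(dr.alpha_se, 1e-6)
    popt, pcov = curve_fit(
        f, c, a, p0=[math.log10(kd0), 1.0],
        bounds=([-15.0, 0.2], [1.0, 4.0]),
        sigma=sigma, absolute_sigma=sigma is not None,
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
    )
    log10_kd, n = popt
    kd = 10.0**log10_kd
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    kd_se = kd * math.log(10.0) * se[0]
    resid = float(np.sum((f(c, *popt) - a) ** 2))
    return HillFit(
        kd=float(kd), n_hill=float(n),
        kd_ci=(kd - 1.96 * kd_se, kd + 1.96 * kd_se),
        n_ci=(n - 1.96 * se[1], n + 1.96 * se[1]),
        residual=resid,
        inhibitor_conc=dr.metadata.get("inhibitor_conc_M"),
    )


def apparent_kd(dr: DoseResponse) -> HillFit:
    """Hill fit of a dose response measured with a fixed inhibitor present;
    the result is labelled apparent with its inhibitor context."""
    if "inhibitor_conc_M" not in dr.metadata:
        raise ValueError("dose response metadata must record 'inhibitor_conc_M'")
    fit = fit_hill(dr)
    fit.apparent = True
    fit.inhibitor_conc = float(dr.metadata["inhibitor_conc_M"])
    return fit


def _collapse_duplicates(T: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq = np.unique(T)
    if len(uniq) == len(T):
        return T, y
    ym = np.array([y[T == t].mean() for t in uniq])
    return uniq, ym


def _line_fit(x: np.ndarray, y: np.ndarray):
    if len(x) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        return slope, intercept, 1.0, np.nan, np.nan
    res = stats.linregress(x, y)
    intercept_se = res.intercept_stderr
    return res.slope, res.intercept, res.rvalue**2, res.stderr, intercept_se


def fit_arrhenius(temperatures_K, rates) -> ArrheniusFit:
    """OLS of ln k on 1/T; Ea = -slope * R.  Duplicate temperatures are
    collapsed to the mean of their ln k."""
    T = np.asarray(temperatures_K, dtype=float)
    k = np.asarray(rates, dtype=float)
    if np.any(k <= 0) or np.any(T <= 0):
        raise ValueError("rates and temperatures must be > 0")
    T, lnk = _collapse_duplicates(T, np.log(k))
    if len(T) < 2:
        raise ValueError("need >= 2 distinct temperatures")
    slope, intercept, r2, slope_se, int_se = _line_fit(1.0 / T, lnk)
    Ea = -slope * R
    Ea_se = (slope_se * R) if np.isfinite(slope_se) else np.nan
    return ArrheniusFit(
        Ea=float(Ea), lnA=float(intercept), r_squared=float(r2),
        Ea_ci=(Ea - 1.96 * Ea_se, Ea + 1.96 * Ea_se),
        lnA_ci=(intercept - 1.96 * int_se, intercept + 1.96 * int_se),
    )


def fit_vant_hoff(temperatures_K, K) -> VantHoffFit:
    """OLS of ln K on 1/T in the dissociation orientation;
    dH = -slope * R, dS = intercept * R."""
    T = np.asarray(temperatures_K, dtype=float)
    Kv = np.asarray(K, dtype=float)
    if np.any(Kv <= 0) or np.any(T <= 0):
        raise ValueError("equilibrium constants and temperatures must be > 0")
    T, lnK = _collapse_duplicates(T, np.log(Kv))
    if len(T) < 2:
        raise ValueError("need >= 2 distinct temperatures")
    slope, intercept, r2, slope_se, int_se = _line_fit(1.0 / T, lnK)
    dH = -slope * R
    dS = intercept * R
    dH_se = (slope_se * R) if np.isfinite(slope_se) else np.nan
    dS_se = (int_se * R) if np.isfinite(int_se) else np.nan
    return VantHoffFit(
        dH=float(dH), dS=float(dS), r_squared=float(r2),
        dH_ci=(dH - 1.96 * dH_se, dH + 1.96 * dH_se),
        dS_ci=(dS - 1.96 * dS_se, dS + 1.96 * dS_se),
    )


def equilibrium_constants(per_temperature: dict) -> list[EquilibriumConstant]:
    """Dissociation equilibrium constants from per-temperature dwell taus.

    ``per_temperature`` maps temperature (K) to ``(tau_bound, tau_unbound)``
    in seconds; ``K_diss = k_diss / k_bind = tau_unbound / tau_bound``.
    Temperatures with a missing tau are skipped with a warning.
    """
    out = []
    for T in sorted(per_temperature):
        taus = per_temperature[T]
        try:
            tau_bound, tau_unbound = taus
        except (TypeError, ValueError):
            tau_bound = tau_unbound = None
        if not tau_bound or not tau_unbound:
            warnings.warn(f"missing bound/unbound tau at T={T} K; skipped")
            continue
        out.append(EquilibriumConstant(K_diss=float(tau_unbound) / float(tau_bound), temperature=float(T)))
    return out
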
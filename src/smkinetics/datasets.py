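"""Multi-condition synthetic datasets: dose series, temperature series,
competition grids.

Every trace carries full condition metadata and a distinct substream seed
derived deterministically from the top-level seed via ``SeedSequence``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .schemes import KineticScheme
from .signals import AcquisitionSpec, CurrentTrace, NoiseSpec, default_noise, render_trace
from .simulate import RateModulation, StatePath, simulate_path
from .units import celsius_to_kelvin, parse_concentration


@dataclass
class Condition:
    """One experimental condition of a dataset grid."""

    temperature_K: float = 310.15
    concentrations: dict[str, float] = field(default_factory=dict)
    pH: float = 7.4
    replicate: int = 0

    def label(self) -> str:
        conc = ",".join(f"{k}={v:.3g}M" for k, v in sorted(self.concentrations.items()))
        return f"T={self.temperature_K:.2f}K;{conc};rep{self.replicate}"


@dataclass
class SimulatedTrace:
    """A rendered trace together with its ground-truth path and condition."""

    condition: Condition
    path: StatePath
    trace: CurrentTrace
    seed: int


def _validate_concentrations(values) -> list[float]:
    concs = [parse_concentration(v) for v in values]
    if any(c2 <= c1 for c1, c2 in zip(concs, concs[1:])):
        raise ValueError(f"concentrations must be strictly increasing, got {values}")
    return concs


def _validate_temperatures(temps_K) -> list[float]:
    temps = [float(t) for t in temps_K]
    for t in temps:
        if not 273.0 <= t <= 350.0:
            raise ValueError(f"temperatures must lie in 273-350 K, got {t} K in temperatures")
    return temps


def make_dataset(
    scheme: KineticScheme,
    acq: AcquisitionSpec,
    noise: NoiseSpec | None = None,
    dose: dict | None = None,
    temperatures_K=None,
    temperatures_C=None,
    fixed_concentrations: dict[str, float] | None = None,
    temperature_K: float = 310.15,
    pH: float = 7.4,
    n_traces: int = 1,
    seed=None,
    modulation: RateModulation | None = None,
    render: bool = True,
) -> list[SimulatedTrace]:
    """Simulate one or more traces per condition over a condition grid.

    ``dose`` is ``{"species": name, "concentrations": [...]}`` (strictly
    increasing, strings like "5 nM" accepted).  ``temperatures_K`` /
    ``temperatures_C`` give a temperature series (validated to 273-350 K).
    Both axes combine as a grid; ``fixed_concentrations`` holds the other
    ligands constant (e.g. a fixed inhibitor in a competition dose series).
    With ``render=False`` only ground-truth paths are produced.
    """
    if noise is None and render:
        noise = default_noise(scheme)
    if temperatures_C is not None:
        temperatures_K = [celsius_to_kelvin(t) for t in temperatures_C]
    temps = _validate_temperatures(temperatures_K) if temperatures_K is not None else [temperature_K]
    if dose is not None:
        species = dose["species"]
        concs = _validate_concentrations(dose["concentrations"])
        conc_axis = [{species: c} for c in concs]
    else:
        conc_axis = [{}]
    fixed = {k: parse_concentration(v) for k, v in (fixed_concentrations or {}).items()}

    conditions = []
    for T, cdict, rep in itertools.product(temps, conc_axis, range(n_traces)):
        conditions.append(Condition(temperature_K=T, concentrations={**fixed, **cdict}, pH=pH, replicate=rep))

    children = np.random.SeedSequence(seed).spawn(len(conditions))
    out = []
    for cond, child in zip(conditions, children):
        sub = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub)
        path = simulate_path(
            scheme,
            acq.duration,
            T=cond.temperature_K,
            concentrations=cond.concentrations,
            seed=rng,
            modulation=modulation,
        )
        if render:
            trace = render_trace(
                path,
                scheme,
                noise=noise,
                acq=acq,
                seed=rng,
                metadata={
                    "temperature_K": cond.temperature_K,
                    "pH": cond.pH,
                    "concentrations": dict(cond.concentrations),
                    "seed": sub,
                    "scheme_id": scheme.scheme_id,
                    "replicate": cond.replicate,
                },
            )
        else:
            trace = None
        out.append(SimulatedTrace(condition=cond, path=path, trace=trace, seed=sub))
    return out
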
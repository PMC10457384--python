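"""End-to-end pipeline: simulate -> idealize -> segment -> fit.

A :class:`RunConfig` (YAML-friendly dict) defines the kinetic scheme, noise
and acquisition, the condition grid (dose series and/or temperature series),
the analysis options and the top-level seed.  ``run_pipeline`` executes the
stages, writes every artifact with provenance (config hash, seed, package
version) and returns the results bundle as a dict.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .datasets import make_dataset
from .dwells import segment_dwells, uncensored_durations
from .hmm import fit_hmm, select_n_states, viterbi
from .io import save_dwell_table, save_trace, write_json
from .kinetics import compute_kobs, fit_induced_fit
from .mixtures import fit_exponential_mixture
from .schemes import KineticScheme, build_apo_scheme, build_binding_scheme, build_competition_scheme
from .signals import AcquisitionSpec, NoiseSpec, default_noise
from .thermo import DoseResponse, HillFit, bound_fraction, equilibrium_constants, fit_arrhenius, fit_hill, fit_vant_hoff
from .units import parse_concentration

logger = logging.getLogger(__name__)

_SCHEME_BUILDERS = {
    "binding": build_binding_scheme,
    "apo": build_apo_scheme,
    "competition": build_competition_scheme,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    scheme: dict
    acquisition: dict
    noise: dict | None = None
    conditions: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "scheme" not in raw or "acquisition" not in raw:
            raise ValueError("config requires 'scheme' and 'acquisition' sections")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme, "acquisition": self.acquisition, "noise": self.noise,
            "conditions": self.conditions, "analysis": self.analysis,
            "seed": self.seed, "outdir": self.outdir,
        }

    def hash(self) -> str:
        content = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        canon = json.dumps(content, sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_scheme_from_config(spec: dict) -> KineticScheme:
    kind = spec.get("type")
    if kind not in _SCHEME_BUILDERS:
        raise ValueError(f"unknown scheme type {kind!r}; choose from {sorted(_SCHEME_BUILDERS)}")
    params = {k: v for k, v in spec.items() if k != "type"}
    return _SCHEME_BUILDERS[kind](**params)


def _stage(name: str, condition: str = ""):
    """Context wrapper: log timing, convert failures to stage-named errors."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise RuntimeError(
                    f"pipeline stage '{name}' failed"
                    + (f" for condition {condition}" if condition else "")
                    + f": {exc}"
                ) from exc
            logger.info("stage %-12s %s done in %.2f s", name, condition, dt)

    return _Ctx()


def run_pipeline(config: RunConfig | dict, save_traces: bool = False) -> dict:
    """Run the full chain and write the results bundle to ``config.outdir``.

    Deterministic given the seed.  Dose-series conditions yield a Hill fit;
    temperature-series conditions yield Arrhenius and van't Hoff fits; both
    axes also produce per-condition dwell fits and, when requested, a k_obs
    curve with an induced-fit fit.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "package_version": __version__,
    }

    with _stage("simulate"):
        scheme = build_scheme_from_config(config.scheme)
        acq = AcquisitionSpec(**config.acquisition)
        noise = NoiseSpec(**config.noise) if config.noise else default_noise(scheme)
        cond = config.conditions
        records = make_dataset(
            scheme, acq, noise=noise,
            dose=cond.get("dose"),
            temperatures_C=cond.get("temperatures_C"),
            temperatures_K=cond.get("temperatures_K"),
            fixed_concentrations=cond.get("fixed_concentrations"),
            temperature_K=cond.get("temperature_K", 310.15),
            pH=cond.get("pH", 7.4),
            n_traces=cond.get("n_traces", 1),
            seed=config.seed,
        )

    ana = config.analysis
    n_states = ana.get("n_states")
    dead_time = ana.get("dead_time_samples", 2)
    n_comp = ana.get("mixture_components", 1)
    n_boot = ana.get("bootstrap", 0)
    bound_state = ana.get("bound_state")

    dwell_tables = []
    idealized_by_cond = {}
    for i, rec in enumerate(records):
        label = rec.condition.label()
        with _stage("idealize", label):
            if n_states is None:
                n_fit, _ = select_n_states(rec.trace, range(1, min(scheme.n_states, 6) + 1), seed=rec.seed)
            else:
                n_fit = n_states
            hmm = fit_hmm(rec.trace, n_fit, seed=rec.seed)
            ideal = viterbi(rec.trace, hmm)
        with _stage("segment", label):
            df = segment_dwells(
                ideal, dead_time=dead_time, trace_id=f"trace{i:03d}",
                metadata={
                    "temperature_K": rec.condition.temperature_K,
                    **{f"conc_{k}_M": v for k, v in rec.condition.concentrations.items()},
                },
            )
        dwell_tables.append(df)
        idealized_by_cond.setdefault(
            (rec.condition.temperature_K, tuple(sorted(rec.condition.concentrations.items()))), []
        ).append(ideal)
        if save_traces:
            save_trace(rec.trace, outdir / f"trace{i:03d}.h5")

    import pandas as pd

    all_dwells = pd.concat(dwell_tables, ignore_index=True)
    save_dwell_table(all_dwells, outdir / "dwells.csv")

    results: dict = {"provenance": provenance, "conditions": len(idealized_by_cond)}

    # per-condition dwell fits for the two lowest-mean states (bound = last index)
    fits = {}
    bound_idx = bound_state if bound_state is not None else scheme.n_states - 1
    dt_s = dead_time / acq.sampling_rate
    for key, ideals in idealized_by_cond.items():
        T_K, concs = key
        dfs = [t for t in dwell_tables if np.isclose(t["temperature_K"].iloc[0], T_K)]
        sub = pd.concat(
            [t for t in dwell_tables
             if np.isclose(t["temperature_K"].iloc[0], T_K)
             and all(np.isclose(t.get(f"conc_{k}_M", pd.Series([np.nan])).iloc[0], v) for k, v in concs)],
            ignore_index=True,
        )
        entry = {}
        for state in range(max(int(sub["state"].max()) + 1, 1) if len(sub) else 0):
            dur = uncensored_durations(sub, state)
            if len(dur) >= 10:
                with _stage("dwell-fit", f"T={T_K} state={state}"):
                    fit = fit_exponential_mixture(dur, n_comp, dead_time=dt_s, seed=config.seed, n_boot=n_boot, state=state)
                entry[state] = {
                    "taus_s": list(fit.taus), "weights": list(fit.weights), "n_dwells": fit.n_dwells,
                }
        fits[f"T={T_K:.2f};{dict(concs)}"] = entry
        results.setdefault("_dwell_fits_raw", {})[key] = entry
    results["dwell_fits"] = fits

    # dose-response -> Hill
    if cond.get("dose"):
        with _stage("fit-hill"):
            species = cond["dose"]["species"]
            concs = [parse_concentration(c) for c in cond["dose"]["concentrations"]]
            alphas, ses = [], []
            for c in concs:
                ideals = [
                    v for key, vals in idealized_by_cond.items() for v in vals
                    if dict(key[1]).get(species) == c
                ]
                bf = bound_fraction(ideals, bound_idx)
                alphas.append(bf.alpha)
                ses.append(max((bf.ci[1] - bf.ci[0]) / (2 * 1.96), 1e-4))
            fixed = cond.get("fixed_concentrations") or {}
            meta = {}
            if "inhibitor" in fixed:
                meta["inhibitor_conc_M"] = parse_concentration(fixed["inhibitor"])
            dr = DoseResponse(np.array(concs), np.array(alphas), np.array(ses), metadata=meta)
            hill = fit_hill(dr)
            results["hill"] = {
                "kd_M": hill.kd, "n_hill": hill.n_hill, "kd_ci_M": list(hill.kd_ci),
                "apparent": bool(meta), "alpha_bind": alphas,
            }

    # temperature series -> Arrhenius + van't Hoff (two-state binding schemes)
    temps = cond.get("temperatures_C") or cond.get("temperatures_K")
    if temps and scheme.n_states == 2:
        with _stage("fit-arrhenius"):
            per_T = {}
            for key, entry in results["_dwell_fits_raw"].items():
                T_K = key[0]
                tau_unbound = entry.get(0, {}).get("taus_s", [None])[0]
                tau_bound = entry.get(1, {}).get("taus_s", [None])[0]
                if tau_bound and tau_unbound:
                    per_T[T_K] = (tau_bound, tau_unbound)
            Ts = sorted(per_T)
            if len(Ts) >= 2:
                k_diss = [1.0 / per_T[t][0] for t in Ts]
                k_bind = [1.0 / per_T[t][1] for t in Ts]
                arr_d = fit_arrhenius(Ts, k_diss)
                arr_b = fit_arrhenius(Ts, k_bind)
                eqs = equilibrium_constants(per_T)
                vh = fit_vant_hoff([e.temperature for e in eqs], [e.K_diss for e in eqs])
                results["arrhenius"] = {
                    "Ea_diss_J_mol": arr_d.Ea, "Ea_bind_J_mol": arr_b.Ea,
                    "lnA_diss": arr_d.lnA, "lnA_bind": arr_b.lnA,
                }
                results["vant_hoff"] = {"dH_diss_J_mol": vh.dH, "dS_diss_J_mol_K": vh.dS}

    # optional k_obs
    if ana.get("kobs") and cond.get("dose"):
        with _stage("fit-kobs"):
            species = cond["dose"]["species"]
            by_conc = {}
            for key, ideals in idealized_by_cond.items():
                c = dict(key[1]).get(species)
                if c is not None:
                    by_conc.setdefault(c, []).extend(ideals)
            curve = compute_kobs(by_conc, bound_idx)
            iff = fit_induced_fit(curve)
            results["kobs"] = {
                "concentrations_M": list(curve.concentrations), "k_obs_per_s": list(curve.k_obs),
                "induced_fit": {"k_f": iff.k_f, "k_r": iff.k_r, "K_1_M": iff.K_1},
            }

    results.pop("_dwell_fits_raw", None)
    write_json(results, outdir / "results.json")
    _write_report(results, outdir / "report.md")
    return results


def _write_report(results: dict, path: Path) -> None:
    lines = ["# Kinetic analysis report", ""]
    prov = results["provenance"]
    lines += [
        f"- config hash: `{prov['config_hash']}`",
        f"- seed: {prov['seed']}",
        f"- package version: {prov['package_version']}",
        "",
    ]
    if "hill" in results:
        h = results["hill"]
        label = "apparent K_D" if h["apparent"] else "K_D"
        lines += [
            "## Dose response (Hill fit)",
            f"- {label} = {h['kd_M']:.4g} M (95% CI {h['kd_ci_M'][0]:.3g}-{h['kd_ci_M'][1]:.3g})",
            f"- Hill n = {h['n_hill']:.3f}",
            "",
        ]
    if "arrhenius" in results:
        a = results["arrhenius"]
        lines += [
            "## Arrhenius",
            f"- Ea (dissociation) = {a['Ea_diss_J_mol'] / 1e3:.1f} kJ/mol",
            f"- Ea (binding) = {a['Ea_bind_J_mol'] / 1e3:.1f} kJ/mol",
            "",
        ]
    if "vant_hoff" in results:
        v = results["vant_hoff"]
        lines += [
            "## van't Hoff (dissociation orientation)",
            f"- dH = {v['dH_diss_J_mol'] / 1e3:.1f} kJ/mol",
            f"- dS = {v['dS_diss_J_mol_K']:.1f} J/(mol K)",
            "",
        ]
    if "kobs" in results:
        kf = results["kobs"]["induced_fit"]
        lines += [
            "## Observed binding rate (induced-fit fit)",
            f"- k_f = {kf['k_f']:.3g} /s, k_r = {kf['k_r']:.3g} /s, K_1 = {kf['K_1_M']:.3g} M",
            "",
        ]
    lines += ["## Dwell fits", "```json", json.dumps(results.get("dwell_fits", {}), indent=2), "```"]
    path.write_text("\n".join(lines))
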
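# smkinetics

Simulation and kinetic analysis of single-molecule conductance traces.

Single-molecule field-effect sensors record the conformational and binding
dynamics of one tethered molecule — for example an intrinsically disordered
protein domain folding, meeting its partner through an encounter
intermediate, and forming a bound complex — as a current that hops between
a few discrete levels, sampled at tens of kHz behind a 10 kHz low-pass
filter and buried in white + 1/f noise. `smkinetics` is a tested, reusable
pipeline for that class of data, aimed at experimentalists and modellers
who need to go from raw (or simulated) traces to kinetic and thermodynamic
constants:

1. **Generative model** — continuous-time Markov kinetic schemes with
   per-transition Arrhenius parameters `k(T) = A·e^(−Ea/RT)` and
   pseudo-first-order association `k_on·C`; exact Gillespie simulation,
   optional slow rate modulation (dynamic disorder).
2. **Signal synthesis** — piecewise-constant conductance levels integrated
   onto a fine grid, Gaussian white + 1/f^β noise, causal Bessel low-pass,
   decimation to 57.6/28.8 kHz.
3. **Idealization** — Gaussian-emission hidden Markov model (Baum–Welch EM,
   Viterbi decoding, BIC state-count selection), verified against exhaustive
   path enumeration, plus a half-amplitude threshold baseline.
4. **Dwell kinetics** — dead-time-aware (left-truncated) exponential-mixture
   MLE, BIC component selection, bootstrap CIs, per-second dynamic-disorder
   statistics, bound-state entry rates `k_obs(C)` with an induced-fit fit
   `k_obs = k_r + k_f·C/(K_1 + C)`.
5. **Thermodynamics** — bound-state populations, Hill fits
   `α = Cⁿ/(K_Dⁿ + Cⁿ)`, Arrhenius activation energies, van't Hoff ΔH/ΔS in
   the dissociation orientation (`K_diss = τ_unbound/τ_bound`), and apparent
   K_D under competing ligands (with a purely competitive Cheng–Prusoff
   variant, `K_D,app = K_D(1 + [I]/K_I)`, as an analytic oracle).

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

A five-point dose series of a bistate binding equilibrium (K_D = 205 nM,
k_off = 200 s⁻¹, i.e. 5 ms mean bound dwells), 2 s of 28.8 kHz trace per
concentration, idealized with a 2-state HMM and fitted end-to-end:

```python
import smkinetics as sk

results = sk.run_pipeline({
    "scheme": {"type": "binding", "kd": 2.05e-7, "k_off": 200.0},
    "acquisition": {"sampling_rate": 28800.0, "duration": 2.0},
    "conditions": {"dose": {"species": "partner",
        "concentrations": ["50 nM", "100 nM", "205 nM", "500 nM", "2 uM"]}},
    "analysis": {"n_states": 2, "dead_time_samples": 2},
    "seed": 11,
    "outdir": "demo",
})
print(results["hill"]["kd_M"], results["hill"]["n_hill"])
```

The run writes `demo/dwells.csv`, `demo/results.json` and `demo/report.md`;
the report begins:

```
# Kinetic analysis report

- config hash: `3b67b2b14025a59f`
- seed: 11
- package version: 0.1.0

## Dose response (Hill fit)
- K_D = 2.025e-07 M (95% CI 2.01e-07-2.04e-07)
- Hill n = 0.979
```

The fitted K_D of 202.5 nM recovers the simulated 205 nM within 1.2%, and
the Hill coefficient is consistent with 1:1 binding. The per-condition
dwell fits in the same report show the bound-state dwell near its 5 ms
truth at every concentration, while the unbound dwell shortens from ~21 ms
at 50 nM to ~0.5 ms at 2 µM — the pseudo-first-order signature
`1/τ_unbound = k_on·C`.

The same stages are scriptable from the shell (`smkin simulate`,
`smkin idealize`, `smkin dwell`, `smkin fit-hill`, `smkin fit-arrhenius`,
`smkin fit-vanthoff`, `smkin fit-kobs`, `smkin run`, `smkin report`).

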
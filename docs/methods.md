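# Methods

`smkinetics` simulates and analyses single-molecule conductance recordings
of the kind produced by a field-effect sensor carrying one molecule: a
piecewise-constant current that hops between a few discrete levels as the
molecule folds, unfolds, and binds partners. The package covers the full
chain — generative kinetic model, signal synthesis, trace idealization,
dwell-time statistics, and binding/thermodynamic parameter estimation —
with every stage testable against ground truth or a closed form.

## Generative model

A **kinetic scheme** is a continuous-time Markov chain: named states, each
with a relative conductance level (baseline 1.0), and a generator matrix
`Q` (s⁻¹). Two dressings make it physical:

* **Arrhenius transitions** carry `(A, Ea)`; the rate at temperature `T` is
  `k(T) = A·exp(−Ea/(R·T))` with `R = 8.314 J/(mol·K)`. Stored `Q` entries
  are the rates at the reference temperature `T_ref = 310.15 K` (37 °C, the
  condition at which binding experiments are typically run), and the
  constructor verifies `Q[i,j] = A·exp(−Ea/(R·T_ref))`.
* **Pseudo-first-order transitions** are bimolecular associations: the
  stored entry is `k_on` in 1/(M·s) and the effective rate at ligand
  concentration `C` is `k_on·C`.

The stationary distribution solves `πQ = 0, Σπ = 1`. Chains with a single
closed communicating class are accepted even when transient states exist
(they get zero mass) — this is what a competition scheme at zero inhibitor
concentration looks like; two or more closed classes are an error, because
the stationary law is then ambiguous.

Three builders cover the systems of interest:

* `build_binding_scheme(kd, k_off)` — the bistate binding equilibrium
  between an encounter intermediate and the fully folded bound complex,
  with `k_on = k_off/kd`. Default `kd = 205 nM`, `k_off = 200 s⁻¹`
  (millisecond bound dwells).
* `build_apo_scheme()` — the free-molecule self-folding scheme: a linear
  0 ↔ 1 ↔ 2 chain of progressively folded intermediates plus a parallel 1*
  branch off the disordered state. States 1 and 1* share the medium current
  level but differ in exit rate (100 µs vs 500 µs mean dwells by default),
  so the medium level's dwell histogram is a two-component exponential
  mixture — the observable signature of a hidden parallel intermediate.
  The exact interconnection topology of such intermediates is not uniquely
  identifiable from level sequences alone; the linear-chain-plus-branch
  default is the simplest scheme reproducing the observed phenomenology.
* `build_competition_scheme(kd_partner, kd_inhibitor, topology=...)` —
  mutually exclusive binding of two ligands. `topology="shared"` is the
  textbook purely competitive star (one unbound state), whose stationary
  occupancy obeys the Cheng–Prusoff relation
  `K_D,app = K_D·(1 + [I]/K_I)` exactly — used as an oracle.
  `topology="distinct"` (default) routes each ligand through its own
  encounter-intermediate state, the mechanism supported by competition
  recordings; it right-shifts the partner dose-response without obeying
  Cheng–Prusoff exactly. Branch rates are calibrated so each branch alone
  half-saturates (relative to its plateau `b/(1+b)`, `b` = fold/unbind
  ratio, default 4) at its nominal `K_D`.

## Simulation

`simulate_path` draws exact Gillespie trajectories: dwell in state *i* is
exponential with the total exit rate, the successor is chosen
proportionally to `Q[i,j]`, and an entered absorbing state holds for the
remaining time. Sampling is bit-reproducible given a seed;
multi-condition datasets derive per-trace substreams from the top-level
seed via `numpy.random.SeedSequence`.

**Dynamic disorder** — slow fluctuation of rate constants — is modelled by
multiplying all rates by a common slow factor, which stretches dwells
without changing stationary occupancy:

* `two_regime`: deterministic alternation between `√a` and `1/√a` every
  `timescale` seconds (mean-dwell fold-change `a` between regimes);
* `lognormal_ou`: `exp` of an Ornstein–Uhlenbeck process with correlation
  time `timescale` and stationary σ = `ln(a)/2`, updated on a
  `timescale/5` grid.

Dwells across regime boundaries consume hazard segment by segment, so the
sampling stays exact for the piecewise-constant rate profile.

## Trace rendering

`render_trace` turns a path into what an acquisition chain records:

1. The level function is **integrated** onto a fine internal grid at 4× the
   sampling rate, so dwells shorter than a grid step contribute their exact
   time-weighted average (as a real ADC would see them); a logged warning
   counts such dwells.
2. Gaussian white noise (per fine-grid sample) and 1/f^β pink noise are
   added. Pink noise is synthesized in the Fourier domain — complex
   Gaussian rfft coefficients shaped by `f^(−β/2)`, zero DC — and rescaled
   to the requested standard deviation; its Welch periodogram slope is −β
   by construction and is property-tested for β ∈ {0.5, 1, 1.5}.
3. A causal low-pass **Bessel** filter (default 4-pole at 10 kHz; Bessel
   for its flat group delay, which minimizes ringing at dwell edges) is
   applied on the fine grid, and the result is decimated to the sampling
   rate (default 57.6 kHz; 28.8 kHz also standard).

Traces are in relative conductance. Defaults drop the level by 3% per
partial-folding step and 6% for the fully bound complex — bound < partially
folded < disordered, the ordering imposed by positive-charge gating of a
p-type nanowire. The recordings this emulates do not quantify absolute
level separations or noise amplitudes, so the default noise is an
engineering choice: white SD = (smallest level separation)/5 ("SNR 5"),
pink amplitude = half the white SD. What passing tests show is therefore
that the *method* recovers known truth under realistic noise — not that
any particular real device meets these SNR figures. Features of real
recordings that the generator deliberately omits: baseline drift,
telegraph noise from the sensor itself, temperature-dependent level
positions, and non-Markovian dwell correlations beyond the explicit slow
modulation.

## Idealization

`fit_hmm` fits a Gaussian-emission hidden Markov model by Baum–Welch EM.
The forward/backward recursions use per-frame max-shifting plus scaling
constants (log-likelihood accumulated in the log domain), which is
numerically equivalent to a pure log-space implementation and faster; the
recursions are compiled with numba because traces run to millions of
samples. Correctness is anchored two ways: the forward log-likelihood and
Viterbi path are tested against exhaustive enumeration over all hidden
paths (T ≤ 8, n ≤ 3), and the forward score is cross-checked against an
independent HMM library on the same parameters.

Initialization (deterministic given the seed): emission means at evenly
spaced quantiles of the sample distribution, SDs at pooled SD/√n, 0.99
self-transitions. Convergence at Δloglik < 1e-6 nats/sample, max 500
iterations; per-iteration monotonicity is asserted to 1e-9 slack. Variance
collapse triggers up to three jittered restarts, then an error. States are
always relabelled by descending mean, so state 0 is the highest-current
level. A known limitation of quantile initialization: a level occupied for
only a tiny time fraction can be missed in favour of splitting the
dominant level; balanced-occupancy traces do not show this.

`select_n_states` chooses the state count by BIC
(`p = n² + 2n − 1` free parameters). `viterbi` decodes the MAP path with
ties broken toward the lower state index. `threshold_idealize` is the
half-amplitude baseline kept as an independent cross-check: nearest level
by midpoint thresholds, midpoint samples assigned to the higher-current
state; on noiseless traces it must agree with Viterbi exactly.

`segment_dwells` run-length encodes the labels; runs of at most
`dead_time` samples (default 2 ≈ 35 µs at 57.6 kHz, safely below genuine
hundred-microsecond events) are merged into the neighbour whose state mean
is nearest, and the clipped first/last dwells are flagged censored and
excluded from fitting by default.

## Dwell-time kinetics

`fit_exponential_mixture` is unbinned maximum likelihood under **left
truncation** at the dead time: observed dwells `x ≥ t0` have density
`Σ wⱼ (1/τⱼ) exp(−(x−t0)/τⱼ)`. For one component the MLE is the closed
form `τ = mean(x − t0)`, which exactly removes the survivor bias of the
naive mean; mixtures are fitted by EM with deterministic quantile
initialization. This truncation correction is adequate for τ ≳ 3× dead
time; full missed-event likelihoods (exact HJC-style corrections) are out
of scope. Unbinned MLE is used rather than histogram fitting because it is
binning-free and efficient; component counts are chosen by BIC
(`p = 2k − 1`). Bootstrap percentile CIs (default 500 resamples, seeded)
propagate to rate constants `k = 1/τ`.

`dynamic_disorder` computes per-window (default 1 s, i.e. second-by-second)
arithmetic mean dwells and their coefficient of variation. For a
homogeneous memoryless process with m dwells per window the CV floor is
1/√m; slow rate modulation pushes the CV above a matched-seed homogeneous
control.

`compute_kobs` counts entries into the bound state per second of
observation. For a two-state binding chain the expectation is the
stationary flux `π_unbound·k_on·C = k_off·C/(C + K_D)` — hyperbolically
increasing in ligand concentration. `fit_induced_fit` fits
`k_obs(C) = k_r + k_f·C/(K_1 + C)`, the standard increasing observed-rate
form of a two-step induced-fit mechanism (chosen over the decreasing form
typical of conformational selection; this functional form is an
interpretive choice, documented here because the mechanism itself is the
open scientific question). Flat curves are flagged non-identifiable.

## Binding thermodynamics

* `bound_fraction`: time fraction of samples labelled bound, pooled over
  traces, with a Wilson score interval. Computed from idealized labels
  rather than raw histogram areas because labels are deterministic and
  ground-truth-testable; a histogram-threshold variant can be obtained by
  thresholding the raw trace with `threshold_idealize`.
* `fit_hill`: least squares of `α(C) = Cⁿ/(K_Dⁿ + Cⁿ)` in `(log₁₀K_D, n)`,
  n bounded to [0.2, 4] and *fitted*, not fixed at 1 (reports can flag when
  the CI for n excludes 1); inverse-variance weights when per-point SEs
  exist. `apparent_kd` is the same estimator with the fixed inhibitor
  concentration recorded in the result.
* `fit_arrhenius`: OLS of ln k on 1/T, `Ea = −slope·R`; duplicate
  temperatures collapse to their mean ln k.
* `fit_vant_hoff`: OLS of ln K on 1/T fitted in the **dissociation
  orientation** (`K_diss = k_diss/k_bind = τ_unbound/τ_bound`), so the
  dissociation of a stable complex yields positive ΔH and ΔS. The fitted
  line satisfies ΔG(T) = ΔH − TΔS = −RT·ln K_pred(T) identically.
  In a strict two-state model ΔH_diss equals Ea_diss − Ea_bind, so a
  simulated temperature series is internally consistent by construction;
  experimental systems with hidden states need not be.

Temperatures are Kelvin internally; Celsius and concentration strings
("5 nM", "1 uM") are accepted at interfaces.

## Problem sizes and numerical choices

The validation suite runs the full chain at the scale the method is meant
for: 60 s of 57.6 kHz trace (3.46 M samples) for two-state dwell recovery
(expected within 10% of truth), 7-concentration dose series for the
cross-route K_D comparison (Hill vs dwell analysis, within 10%),
5-temperature series in triplicate for Arrhenius/van't Hoff, and 100-seed
replicate batches for CI coverage and dynamic-disorder detection. Exact
inversions (noiseless Hill, Arrhenius, van't Hoff, hyperbolic k_obs) are
required to 1e-6 relative or better. Tolerances on stochastic checks are
3 Monte-Carlo standard errors unless a wider figure is stated with the
check.

Tie-breaks and degenerate inputs: Viterbi ties go to the lower state
index; threshold midpoints go to the higher-current state; a blip
equidistant between two neighbours merges into the earlier one; mixture
components are reported in ascending τ; EM variance collapse restarts
seeded; all-zero or all-one dose responses and flat k_obs curves raise or
flag rather than returning arbitrary numbers.

## Known limitations

* No missed-event correction beyond dead-time truncation; no baseline
  drift or noise whitening.
* The HMM assumes independent Gaussian emissions; low-pass filtering
  correlates neighbouring samples, which mildly biases transition-rate
  estimates from per-sample transition probabilities — dwell-based rate
  estimation (the supported route) is insensitive to this.
* Hill fits assume the bound fraction saturates at 1; schemes whose bound
  branch plateaus below 1 (e.g. the distinct-intermediate competition
  topology) yield effective, not mechanistic, parameters.
* The induced-fit form of `k_obs(C)` is one of several mechanisms
  compatible with an increasing observed rate.
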
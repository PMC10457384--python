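"""Binding thermodynamics: bound fractions, Hill, Arrhenius, van't Hoff,
equilibrium constants, competition."""

import numpy as np
import pytest

import smkinetics as sk
from smkinetics.hmm import IdealizedTrace
from smkinetics.units import R

from conftest import two_state_scheme


def _ideal(labels, fs=1000.0):
    return IdealizedTrace(np.array(labels), None, None, fs, means=np.array([1.0, 0.9]))


class TestBoundFraction:
    def test_all_bound_is_one(self):
        bf = sk.bound_fraction(_ideal([1] * 100), bound_state=1)
        assert bf.alpha == 1.0

    def test_noiseless_trace_matches_path_time_fraction(self):
        scheme = two_state_scheme(100.0, 100.0, levels=(1.0, 0.9))
        path = sk.simulate_path(scheme, 5.0, seed=1)
        acq = sk.AcquisitionSpec(sampling_rate=57600.0, filter_cutoff=None, duration=5.0)
        tr = sk.render_trace(path, scheme, sk.NoiseSpec(), acq, seed=0)
        ideal = sk.threshold_idealize(tr, scheme.levels)
        bf = sk.bound_fraction(ideal, bound_state=1)
        truth = path.durations[path.states == 1].sum() / path.total_duration
        assert bf.alpha == pytest.approx(truth, abs=len(path.durations) / (5.0 * 57600.0))

    def test_half_occupancy_at_kd(self, binding_scheme):
        """At C = K_D a 1:1 binding equilibrium sits at alpha = 1/2."""
        path = sk.simulate_path(binding_scheme, 100.0, seed=2, concentrations={"partner": 205e-9})
        frac = path.durations[path.states == 1].sum() / path.total_duration
        n_cycles = np.sum(np.diff(path.states) != 0) / 2
        se = 0.5 / np.sqrt(n_cycles)  # renewal-process scale MC error
        assert abs(frac - 0.5) < 3 * se


class TestHill:
    @pytest.mark.parametrize("kd", [1e-9, 205e-9, 1e-6, 1e-4])
    def test_exact_curve_recovered(self, kd):
        """Noiseless n = 1 Hill curves recover (K_D, 1) to 1e-6 relative."""
        c = kd * np.logspace(-1.5, 1.5, 7)
        dr = sk.DoseResponse(c, c / (c + kd))
        fit = sk.fit_hill(dr)
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        assert fit.n_hill == pytest.approx(1.0, rel=1e-6)

    def test_cooperative_curve_recovered(self):
        kd, n = 3e-7, 1.8
        c = kd * np.logspace(-1.2, 1.2, 8)
        dr = sk.DoseResponse(c, c**n / (kd**n + c**n))
        fit = sk.fit_hill(dr)
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        assert fit.n_hill == pytest.approx(n, rel=1e-6)

    def test_binomial_noise_keeps_kd_in_ci(self):
        """True K_D inside the fitted 95% CI for most binomially sampled replicates."""
        kd = 205e-9
        c = kd * np.logspace(-1.5, 1.5, 7)
        n_eff = 100000
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            alpha = rng.binomial(n_eff, c / (c + kd)) / n_eff
            se = np.sqrt(np.maximum(alpha * (1 - alpha), 1e-6) / n_eff)
            fit = sk.fit_hill(sk.DoseResponse(c, alpha, se))
            hits += fit.kd_ci[0] <= kd <= fit.kd_ci[1]
        assert hits >= 16

    def test_flat_response_rejected(self):
        c = np.logspace(-9, -5, 5)
        with pytest.raises(ValueError, match="flat"):
            sk.fit_hill(sk.DoseResponse(c, np.zeros(5)))

    def test_narrow_range_rejected(self):
        c = np.linspace(1e-7, 5e-7, 5)
        with pytest.raises(ValueError, match="10x"):
            sk.fit_hill(sk.DoseResponse(c, c / (c + 2e-7)))


class TestApparentKd:
    def test_zero_inhibitor_equals_plain_hill(self):
        kd = 205e-9
        c = kd * np.logspace(-1.5, 1.5, 7)
        dr0 = sk.DoseResponse(c, c / (c + kd), metadata={"inhibitor_conc_M": 0.0})
        fit = sk.apparent_kd(dr0)
        assert fit.apparent
        assert fit.kd == pytest.approx(sk.fit_hill(sk.DoseResponse(c, c / (c + kd))).kd, rel=1e-9)

    def test_missing_inhibitor_metadata_rejected(self):
        c = np.logspace(-8, -5, 5)
        with pytest.raises(ValueError, match="inhibitor"):
            sk.apparent_kd(sk.DoseResponse(c, c / (c + 1e-7)))

    def test_purely_competitive_scheme_follows_cheng_prusoff(self):
        """Apparent K_D from stationary occupancies = K_D (1 + [I]/K_I) within 5%."""
        kd, ki, inh = 205e-9, 33e-6, 100e-6
        comp = sk.build_competition_scheme(kd, ki, topology="shared")
        kd_app_true = kd * (1 + inh / ki)
        c = kd_app_true * np.logspace(-1.5, 1.5, 7)
        alpha = np.array(
            [sk.stationary_distribution(comp, concentrations={"partner": ci, "inhibitor": inh})[1] for ci in c]
        )
        fit = sk.apparent_kd(sk.DoseResponse(c, alpha, metadata={"inhibitor_conc_M": inh}))
        assert fit.kd == pytest.approx(kd_app_true, rel=0.05)

    def test_distinct_intermediates_still_right_shift_kd(self):
        """On the encounter-intermediate topology the inhibitor raises the
        apparent K_D above the partner's intrinsic K_D."""
        kd, ki, inh = 205e-9, 33e-6, 100e-6
        comp = sk.build_competition_scheme(kd, ki, topology="distinct")
        b = comp.state_index("bound_partner")
        c = kd * np.logspace(-1, 2.2, 8)
        alpha = np.array(
            [sk.stationary_distribution(comp, concentrations={"partner": ci, "inhibitor": inh})[b] for ci in c]
        )
        fit = sk.apparent_kd(sk.DoseResponse(c, alpha, metadata={"inhibitor_conc_M": inh}))
        assert fit.kd > kd


class TestArrhenius:
    def test_constant_rate_has_zero_activation_energy(self):
        fit = sk.fit_arrhenius([298.15, 308.15, 318.15], [100.0, 100.0, 100.0])
        assert fit.Ea == pytest.approx(0.0, abs=1e-9)

    def test_two_point_closed_form(self):
        """Two points generated from Ea = 100 kJ/mol invert exactly."""
        ea, lnA = 100e3, 30.0
        T = np.array([298.15, 318.15])
        k = np.exp(lnA - ea / (R * T))
        fit = sk.fit_arrhenius(T, k)
        assert fit.Ea == pytest.approx(ea, rel=1e-12)
        assert fit.lnA == pytest.approx(lnA, rel=1e-12)

    def test_noisy_rates_recover_ea_within_fifteen_percent(self):
        ea, lnA = 109e3, 36.0
        T = 273.15 + np.arange(25, 50, 5)
        rng = np.random.default_rng(0)
        k = np.exp(lnA - ea / (R * T)) * np.exp(rng.normal(0, 0.05, len(T)))
        fit = sk.fit_arrhenius(T, k)
        assert fit.Ea == pytest.approx(ea, rel=0.15)

    def test_duplicate_temperatures_collapse(self):
        fit = sk.fit_arrhenius([298.15, 298.15, 318.15], [90.0, 110.0, 400.0])
        ref = sk.fit_arrhenius([298.15, 318.15], [np.exp(np.mean(np.log([90.0, 110.0]))), 400.0])
        assert fit.Ea == pytest.approx(ref.Ea)


class TestVantHoff:
    def test_constant_k_gives_zero_enthalpy(self):
        fit = sk.fit_vant_hoff([298.15, 308.15, 318.15], [2.0, 2.0, 2.0])
        assert fit.dH == pytest.approx(0.0, abs=1e-9)
        assert fit.dS == pytest.approx(R * np.log(2.0), rel=1e-9)

    def test_exact_data_recovered_to_machine_precision(self):
        dH, dS = 24e3, 50.0
        T = 273.15 + np.arange(25, 50, 5)
        K = np.exp(-dH / (R * T) + dS / R)
        fit = sk.fit_vant_hoff(T, K)
        assert fit.dH == pytest.approx(dH, rel=1e-9)
        assert fit.dS == pytest.approx(dS, rel=1e-9)

    def test_gibbs_identity_holds_at_every_input_temperature(self):
        """dH - T dS = -R T ln K_pred(T) for the fitted line."""
        rng = np.random.default_rng(1)
        T = 273.15 + np.arange(25, 50, 5)
        K = np.exp(-30e3 / (R * T) + 45.0 / R) * np.exp(rng.normal(0, 0.1, len(T)))
        fit = sk.fit_vant_hoff(T, K)
        for t in T:
            lhs = fit.dH - t * fit.dS
            rhs = -R * t * fit.predict_lnK(t)
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestEquilibriumConstants:
    def test_equal_taus_give_unit_constant(self):
        (eq,) = sk.equilibrium_constants({310.15: (2e-3, 2e-3)})
        assert eq.K_diss == 1.0

    def test_missing_tau_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            out = sk.equilibrium_constants({298.15: (2e-3, None), 310.15: (1e-3, 2e-3)})
        assert len(out) == 1
        assert out[0].temperature == 310.15

    def test_two_state_simulation_matches_stationary_ratio(self, binding_scheme):
        """K_diss = tau_unbound/tau_bound equals pi_unbound/pi_bound within 3 MC SEs."""
        c = 205e-9
        path = sk.simulate_path(binding_scheme, 150.0, seed=4, concentrations={"partner": c})
        df = sk.dwells_from_path(path)
        tau_u = sk.uncensored_durations(df, 0)
        tau_b = sk.uncensored_durations(df, 1)
        (eq,) = sk.equilibrium_constants({310.15: (tau_b.mean(), tau_u.mean())})
        pi = sk.stationary_distribution(binding_scheme, concentrations={"partner": c})
        truth = pi[0] / pi[1]
        se = truth * np.sqrt(1 / len(tau_u) + 1 / len(tau_b))
        assert abs(eq.K_diss - truth) < 3 * se

    def test_k_rises_with_temperature_when_dissociation_barrier_higher(self):
        """Ea_diss = 109 > Ea_bind = 71 kJ/mol implies K_diss increasing in T."""
        scheme = sk.build_binding_scheme(205e-9, k_off=200.0, arrhenius={"bind": 71e3, "diss": 109e3})
        Ks = []
        for T in (298.15, 308.15, 318.15):
            Q = sk.rates_at_temperature(scheme, T)
            Ks.append(Q[1, 0] / Q[0, 1])  # k_diss / k_bind (second-order scale cancels in the trend)
        assert np.all(np.diff(Ks) > 0)
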
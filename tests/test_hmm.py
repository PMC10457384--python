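"""HMM idealization: forward/Viterbi vs exhaustive enumeration, EM fitting,
model selection, threshold baseline."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smkinetics as sk

from conftest import brute_force_loglik, brute_force_viterbi, random_hmm, two_state_scheme


def _sample_from_hmm(rng, hmm, T):
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(hmm.n_states, p=hmm.initial_probs)
    for t in range(1, T):
        states[t] = rng.choice(hmm.n_states, p=hmm.transition_probs[states[t - 1]])
    x = rng.normal(hmm.means[states], hmm.sds[states])
    return x, states


class TestForwardLoglik:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 4))
        T = int(rng.integers(4, 9))
        hmm = random_hmm(rng, n)
        x, _ = _sample_from_hmm(rng, hmm, T)
        assert sk.loglik(x, hmm) == pytest.approx(brute_force_loglik(x, hmm), abs=1e-8)

    def test_single_state_is_gaussian_loglik(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.3, 200)
        hmm = sk.GaussianHMM(np.ones(1), np.ones((1, 1)), np.array([0.9]), np.array([0.25]))
        expected = np.sum(-0.5 * ((x - 0.9) / 0.25) ** 2 - np.log(0.25) - 0.5 * np.log(2 * np.pi))
        assert sk.loglik(x, hmm) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_state_relabelling_leaves_loglik_unchanged(self, seed):
        """Permuting states (with matching rows/columns) is a pure relabelling."""
        rng = np.random.default_rng(seed)
        hmm = random_hmm(rng, 3)
        x, _ = _sample_from_hmm(rng, hmm, 20)
        perm = rng.permutation(3)
        ll_orig = sk.loglik(x, hmm)
        # bypass the sorted-means invariant: evaluate the permuted forward sum directly
        from smkinetics.hmm import _forward, _frame_logprob

        logB = _frame_logprob(np.asarray(x, float), hmm.means[perm], hmm.sds[perm])
        ll_perm = _forward(logB, hmm.transition_probs[np.ix_(perm, perm)], hmm.initial_probs[perm])
        assert ll_perm == pytest.approx(ll_orig, abs=1e-9)


class TestViterbi:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 4))
        T = int(rng.integers(4, 9))
        hmm = random_hmm(rng, n)
        x, _ = _sample_from_hmm(rng, hmm, T)
        ideal = sk.viterbi(x, hmm)
        assert np.array_equal(ideal.labels, brute_force_viterbi(x, hmm))

    def test_noiseless_trace_recovers_true_path(self):
        scheme = two_state_scheme(50.0, 50.0, levels=(1.0, 0.9))
        path = sk.simulate_path(scheme, 1.0, seed=2)
        acq = sk.AcquisitionSpec(sampling_rate=10000.0, filter_cutoff=None, duration=1.0)
        tr = sk.render_trace(path, scheme, sk.NoiseSpec(), acq, seed=0)
        hmm = sk.GaussianHMM(
            np.array([0.5, 0.5]), np.array([[0.99, 0.01], [0.01, 0.99]]),
            np.array([1.0, 0.9]), np.array([0.005, 0.005]),
        )
        ideal = sk.viterbi(tr, hmm)
        truth = path.labels_at(tr.times)
        # boundary samples straddle two states; exclude them
        interior = np.ones(len(tr), dtype=bool)
        for _, t0, t1 in path.events():
            for edge in (t0, t1):
                j = int(round(edge * 10000))
                interior[max(j - 1, 0): j + 1] = False
        assert np.array_equal(ideal.labels[interior], truth[interior])

    def test_misassignment_rate_below_one_percent_at_separation_five(self):
        rng = np.random.default_rng(3)
        hmm = sk.GaussianHMM(
            np.array([0.5, 0.5]), np.array([[0.995, 0.005], [0.005, 0.995]]),
            np.array([1.0, 0.95]), np.array([0.01, 0.01]),
        )
        x, states = _sample_from_hmm(rng, hmm, 50000)
        ideal = sk.viterbi(x, hmm)
        assert np.mean(ideal.labels != states) < 0.01


class TestFitHMM:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.97, 0.012, 5000)
        hmm = sk.fit_hmm(x, 1)
        assert hmm.means[0] == pytest.approx(x.mean(), rel=1e-12)
        assert hmm.sds[0] == pytest.approx(x.std(), rel=1e-12)

    def test_two_level_means_recovered_within_one_percent(self):
        """Separation/SD = 5 fixture; fitted means within 1% of true levels."""
        rng = np.random.default_rng(4)
        truth = sk.GaussianHMM(
            np.array([0.5, 0.5]), np.array([[0.99, 0.01], [0.02, 0.98]]),
            np.array([1.0, 0.95]), np.array([0.01, 0.01]),
        )
        x, _ = _sample_from_hmm(rng, truth, 20000)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # EM monotonicity: no decrease warnings
            hmm = sk.fit_hmm(x, 2, seed=0)
        assert hmm.means == pytest.approx(truth.means, rel=0.01)

    def test_transition_probs_recovered(self):
        rng = np.random.default_rng(5)
        truth = sk.GaussianHMM(
            np.array([0.5, 0.5]), np.array([[0.99, 0.01], [0.02, 0.98]]),
            np.array([1.0, 0.94]), np.array([0.012, 0.012]),
        )
        x, _ = _sample_from_hmm(rng, truth, 50000)
        hmm = sk.fit_hmm(x, 2, seed=0)
        assert hmm.transition_probs == pytest.approx(truth.transition_probs, abs=0.005)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="10"):
            sk.fit_hmm(np.zeros(15), 2)


class TestSelectNStates:
    def test_constant_plus_noise_selects_one(self):
        rng = np.random.default_rng(6)
        x = 1.0 + rng.normal(0, 0.01, 4000)
        best, _ = sk.select_n_states(x, range(1, 4), seed=0)
        assert best == 1

    def test_two_level_trace_selects_two(self):
        rng = np.random.default_rng(7)
        truth = sk.GaussianHMM(
            np.array([0.5, 0.5]), np.array([[0.99, 0.01], [0.01, 0.99]]),
            np.array([1.0, 0.94]), np.array([0.01, 0.01]),
        )
        x, _ = _sample_from_hmm(rng, truth, 10000)
        best, bics = sk.select_n_states(x, range(1, 4), seed=0)
        assert best == 2
        assert bics[2] < bics[3]

    def test_apo_like_trace_divides_into_three_states(self):
        """A three-level folding trace decomposes into three current states."""
        states = [sk.KineticState(n, l) for n, l in (("0", 1.0), ("1", 0.97), ("2", 0.94))]
        scheme = sk.KineticScheme.from_rates(
            states, {(0, 1): 1000.0, (1, 0): 1500.0, (1, 2): 800.0, (2, 1): 1200.0}
        )
        path = sk.simulate_path(scheme, 1.5, seed=9)
        acq = sk.AcquisitionSpec(sampling_rate=57600.0, filter_cutoff=None, duration=1.5)
        tr = sk.render_trace(path, scheme, sk.NoiseSpec(white_sd=0.005), acq, seed=1)
        best, _ = sk.select_n_states(tr, range(1, 5), seed=0)
        assert best == 3


class TestThresholdIdealize:
    def test_noiseless_matches_viterbi(self):
        scheme = two_state_scheme(50.0, 50.0, levels=(1.0, 0.9))
        path = sk.simulate_path(scheme, 1.0, seed=12)
        acq = sk.AcquisitionSpec(sampling_rate=10000.0, filter_cutoff=None, duration=1.0)
        tr = sk.render_trace(path, scheme, sk.NoiseSpec(), acq, seed=0)
        hmm = sk.GaussianHMM(
            np.array([0.5, 0.5]), np.array([[0.99, 0.01], [0.01, 0.99]]),
            np.array([1.0, 0.9]), np.array([0.004, 0.004]),
        )
        assert np.array_equal(
            sk.threshold_idealize(tr, [1.0, 0.9]).labels, sk.viterbi(tr, hmm).labels
        )

    def test_midpoint_sample_goes_to_higher_current_state(self):
        ideal = sk.threshold_idealize(np.array([0.95, 0.951, 0.949]), [1.0, 0.9])
        assert list(ideal.labels) == [0, 0, 1]

    def test_high_separation_agreement_with_viterbi(self):
        """At separation/SD = 8 both idealizers agree on >= 99% of samples."""
        rng = np.random.default_rng(13)
        truth = sk.GaussianHMM(
            np.array([0.5, 0.5]), np.array([[0.99, 0.01], [0.01, 0.99]]),
            np.array([1.0, 0.92]), np.array([0.01, 0.01]),
        )
        x, _ = _sample_from_hmm(rng, truth, 30000)
        agree = np.mean(
            sk.threshold_idealize(x, truth.means).labels == sk.viterbi(x, truth).labels
        )
        assert agree >= 0.99


def test_loglik_agrees_with_hmmlearn_oracle():
    """Independent reference: hmmlearn's forward score on the same parameters."""
    from hmmlearn.hmm import GaussianHMM as RefHMM

    rng = np.random.default_rng(21)
    hmm = random_hmm(rng, 3)
    x, _ = _sample_from_hmm(rng, hmm, 500)
    ref = RefHMM(n_components=3, covariance_type="diag", init_params="")
    ref.startprob_ = hmm.initial_probs
    ref.transmat_ = hmm.transition_probs
    ref.means_ = hmm.means[:, None]
    ref.covars_ = (hmm.sds**2)[:, None]
    assert sk.loglik(x, hmm) == pytest.approx(ref.score(x[:, None]), abs=1e-6)
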
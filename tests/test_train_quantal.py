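"""Evoked-train analysis: amplitudes, PPR, cumulative RRP/Pr, kinetics fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from presynquant.io import DataError, train_protocol
from presynquant.simulate import SynapseModel, psc_kernel, render_train_trace, simulate_train
from presynquant.trains import (
    cumulative_profile,
    estimate_rrp_pr,
    fit_depression,
    fit_recovery,
    measure_evoked_amplitudes,
    paired_pulse_ratio,
    ppr_by_isi,
)
from conftest import responses_from_amplitudes

from presynquant.io import Trace


class TestEvokedAmplitudes:
    def test_identical_templates_measured_exactly(self):
        # at 5 Hz the 5 ms decay has fully relaxed before the next baseline
        # window, so the measurement is exact
        proto = train_protocol(5.0, 4.0)
        model = SynapseModel(noise_sd=0.0)
        trace = render_train_trace(np.full(20, 100.0), proto, model)
        responses = measure_evoked_amplitudes(trace, proto)
        amps = np.array([r.amplitude for r in responses])
        np.testing.assert_allclose(amps, 100.0, atol=1e-9)

    def test_40hz_protocol_yields_80_responses(self, rng):
        proto = train_protocol(40.0, 2.0)
        model = SynapseModel(noise_sd=1.0, seed=1)
        trace = render_train_trace(np.full(80, 100.0), proto, model)
        assert len(measure_evoked_amplitudes(trace, proto)) == 80

    def test_simulated_train_amplitudes_match_model(self):
        proto = train_protocol(40.0, 2.0)
        model = SynapseModel(Pr=0.8, noise_sd=1.0, seed=3, q_cv=0.0)
        amps, _ = simulate_train(model, proto, mode="expected")
        trace = render_train_trace(amps, proto, model)
        responses = measure_evoked_amplitudes(trace, proto)
        measured = np.array([r.amplitude for r in responses])
        # each response within a few noise SD plus the ~2% decay-tail overlap
        # (of its own and the preceding response) inherent to measuring 40 Hz
        # responses from a pre-stimulus baseline
        prev = np.concatenate([[0.0], amps[:-1]])
        assert np.all(np.abs(measured - amps) <= 0.02 * (amps + prev) + 6.0)

    def test_isi_shorter_than_blank_rejected(self, rng):
        trace = Trace(samples=rng.normal(size=10000), dt=1e-4)
        proto = train_protocol(1000.0, 0.01, t_start=0.1)
        with pytest.raises(DataError):
            measure_evoked_amplitudes(trace, proto, artifact_blank=0.002)


class TestPairedPulse:
    def test_equal_amplitudes_give_unity(self, make_responses):
        r = make_responses([50.0, 50.0], [0.0, 0.05])
        assert paired_pulse_ratio(r) == pytest.approx(1.0)

    @pytest.mark.parametrize("pr", [0.2, 0.5, 0.9])
    def test_depletion_without_replenishment_gives_1_minus_pr(self, pr, make_responses):
        model = SynapseModel(Pr=pr, replenish_rate=0.0, N_sites=100, q_mean=10.0)
        proto = train_protocol(20.0, 0.1)  # two stimuli, 50 ms apart
        amps, _ = simulate_train(model, proto, mode="expected")
        ppr = paired_pulse_ratio(make_responses(amps, proto.stim_times))
        assert ppr == pytest.approx(1.0 - pr, abs=1e-12)

    def test_isi_grid_aggregation(self, make_responses):
        isis = [0.02, 0.05, 0.1, 0.2, 0.5, 1.0]
        sweeps = [
            (isi, make_responses([100.0, 80.0], [0.0, isi])) for isi in isis
        ] * 2
        table = ppr_by_isi(sweeps)
        assert list(table["isi_s"]) == isis
        assert np.allclose(table["ppr_mean"], 0.8)
        assert (table["n"] == 2).all()

    def test_zero_first_response_flagged_nan(self, make_responses):
        r = make_responses([0.0, 50.0], [0.0, 0.05])
        assert np.isnan(paired_pulse_ratio(r))


class TestCumulativeProfile:
    def test_running_sum(self, make_responses):
        r = make_responses([3.0, 2.0, 1.0], [0.0, 0.025, 0.05])
        cum = cumulative_profile(r)
        np.testing.assert_allclose(cum.cum_amplitudes, [3.0, 5.0, 6.0])

    @given(
        amps=st.lists(st.floats(min_value=0.0, max_value=1e3), min_size=2, max_size=60)
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_for_any_nonnegative_input(self, amps):
        r = responses_from_amplitudes(amps, np.arange(len(amps)) * 0.025)
        cum = cumulative_profile(r)
        assert np.all(np.diff(cum.cum_amplitudes) >= 0)


class TestRRPEstimator:
    def _fit(self, model, proto=None, mode="expected"):
        proto = proto or train_protocol(40.0, 2.0)
        amps, _ = simulate_train(model, proto, mode=mode)
        r = responses_from_amplitudes(amps, proto.stim_times)
        return estimate_rrp_pr(cumulative_profile(r))

    def test_deterministic_oracle_exact(self):
        # Pr=1, N=100, q=10 pA, replenishment 2 sites per ISI: the cumulative
        # curve is exactly linear beyond the first stimulus, so the intercept
        # recovers N*q = 1000 pA and Pr = 1 to machine precision
        model = SynapseModel(
            N_sites=100, q_mean=10.0, Pr=1.0, replenish_rate=80.0, q_cv=0.0
        )
        fit = self._fit(model)
        assert fit.intercept_RRP == pytest.approx(1000.0, abs=1e-9)
        assert fit.Pr == pytest.approx(1.0, abs=1e-12)
        assert fit.valid

    def test_fit_window_selects_stimuli_21_to_40(self):
        proto = train_protocol(40.0, 2.0)
        t_rel = proto.stim_times - proto.stim_times[0]
        mask = (t_rel >= 0.5) & (t_rel < 1.0)
        assert np.flatnonzero(mask)[0] == 20 and np.flatnonzero(mask)[-1] == 39

    def test_constant_amplitudes_invalid(self, make_responses):
        # no depression: the back-extrapolated intercept collapses onto the
        # steady-state single-interval increment (= I1), i.e. there is no
        # measurable pool beyond one interval's refill -> flagged invalid
        r = make_responses([100.0] * 80, np.arange(80) * 0.025)
        fit = estimate_rrp_pr(cumulative_profile(r))
        assert not fit.valid
        assert fit.intercept_RRP == pytest.approx(fit.slope * 0.025, rel=1e-9)

    def test_too_few_points_in_window_errors(self, make_responses):
        r = make_responses([10.0, 5.0, 2.0], [0.0, 0.6, 1.2])
        with pytest.raises(DataError):
            estimate_rrp_pr(cumulative_profile(r))

    def test_scale_equivariance(self):
        m1 = SynapseModel(N_sites=100, q_mean=10.0, Pr=0.8, replenish_rate=80.0)
        m2 = SynapseModel(N_sites=100, q_mean=20.0, Pr=0.8, replenish_rate=80.0)
        f1, f2 = self._fit(m1), self._fit(m2)
        assert f2.intercept_RRP == pytest.approx(2 * f1.intercept_RRP, rel=1e-9)
        assert f2.Pr == pytest.approx(f1.Pr, rel=1e-9)

    def test_underestimation_bias_shrinks_as_pr_rises(self):
        # constant replenishment inflates the steady-state pool at low Pr,
        # pulling the back-extrapolated intercept below N*q; the deficit
        # vanishes as Pr -> 1
        biases = []
        for pr in (0.2, 0.4, 0.6, 0.8, 1.0):
            model = SynapseModel(N_sites=100, q_mean=10.0, Pr=pr, replenish_rate=80.0)
            biases.append(self._fit(model).intercept_RRP - 1000.0)
        assert all(b <= 1e-9 for b in biases)
        assert all(abs(a) > abs(b) - 1e-9 for a, b in zip(biases, biases[1:]))

    def test_stochastic_median_recovery_within_10pct(self):
        proto = train_protocol(40.0, 2.0)
        estimates = [
            self._fit(
                SynapseModel(N_sites=100, q_mean=10.0, Pr=0.8, replenish_rate=80.0, seed=s),
                proto,
                mode="stochastic",
            ).intercept_RRP
            for s in range(50)
        ]
        assert abs(np.median(estimates) / 1000.0 - 1.0) < 0.10


class TestDepressionRecoveryFits:
    def test_biexponential_recovery_noiseless(self, make_responses):
        t = np.arange(600) / 20.0  # 30 s at 20 Hz
        y = 0.2 + 0.5 * np.exp(-t / 0.5) + 0.3 * np.exp(-t / 5.0)
        fit = fit_depression(make_responses(y, t))
        assert fit.model == "biexp"
        assert fit.SSC == pytest.approx(0.2, rel=1e-4)
        assert fit.tau_fast == pytest.approx(0.5, rel=1e-4)
        assert fit.tau_slow == pytest.approx(5.0, rel=1e-4)
        assert fit.A_fast == pytest.approx(0.5, rel=1e-4)
        assert fit.A_slow == pytest.approx(0.3, rel=1e-4)
        assert fit.tau_fast < fit.tau_slow

    def test_constant_train_is_no_depression_limit(self, make_responses):
        t = np.arange(600) / 20.0
        fit = fit_depression(make_responses(np.ones(600), t))
        assert fit.SSC == pytest.approx(1.0, abs=1e-6)
        assert fit.A_fast + fit.A_slow == pytest.approx(0.0, abs=1e-6)

    def test_mono_fallback_on_single_exponential_data(self, make_responses):
        t = np.arange(600) / 20.0
        y = 0.3 + 0.7 * np.exp(-t / 2.0)
        fit = fit_depression(make_responses(y, t))
        assert fit.model == "monoexp"
        assert fit.tau_fast == pytest.approx(2.0, rel=1e-3)

    def test_recovery_noiseless(self, make_responses):
        t = np.arange(0, 600, 10.0)  # 0.1 Hz probes
        y = 0.9 - (0.9 - 0.2) * np.exp(-t / 30.0)
        fit = fit_recovery(make_responses(y, t), I1_pre=1.0, t_train_end=0.0)
        assert fit.SSC == pytest.approx(0.9, rel=1e-4)
        assert fit.tau == pytest.approx(30.0, rel=1e-4)
        assert fit.first_post_response == pytest.approx(0.2, rel=1e-4)

    def test_instant_full_recovery(self, make_responses):
        t = np.arange(0, 100, 10.0)
        fit = fit_recovery(make_responses(np.ones(10), t), I1_pre=1.0)
        assert fit.SSC == pytest.approx(1.0)
        assert fit.first_post_response == pytest.approx(1.0)

    def test_halved_replenishment_lowers_recovery_steady_state(self, make_responses):
        # two simulated genotypes probed at 0.1 Hz after a depressing train:
        # with replenishment slow enough that the pool cannot refill within a
        # probe interval, halving it lowers the recovered steady state by the
        # simulator's own steady-state ratio (rho*ISI/Pr, capped at N)
        proto = train_protocol(20.0, 30.0, probe_freq=0.1, probe_duration=240.0)
        sscs = {}
        for name, rate in (("wt", 4.0), ("mut", 2.0)):
            model = SynapseModel(N_sites=100, q_mean=10.0, Pr=0.35, replenish_rate=rate)
            amps, _ = simulate_train(model, proto, mode="expected")
            r = responses_from_amplitudes(amps, proto.stim_times)
            post = [x for x in r if x.stim_t >= 30.0]
            fit = fit_recovery(post, I1_pre=r[0].amplitude, t_train_end=30.0)
            sscs[name] = fit.SSC
        expected_mut = min(2.0 * 10.0 / 0.35, 100.0) / 100.0  # a_ss/N = 0.571
        assert sscs["mut"] < sscs["wt"]
        assert sscs["mut"] == pytest.approx(expected_mut, rel=0.1)

    def test_noisy_recovery_within_15pct(self, make_responses, rng):
        t = np.arange(600) / 20.0
        y0 = 0.2 + 0.5 * np.exp(-t / 0.5) + 0.3 * np.exp(-t / 5.0)
        errs = []
        for _ in range(20):
            y = y0 * (1 + 0.05 * rng.standard_normal(t.size))
            fit = fit_depression(make_responses(np.abs(y) / abs(y[0]), t))
            errs.append(abs(fit.tau_slow - 5.0) / 5.0)
        assert np.median(errs) < 0.15
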
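"""Miniature-event detector: thresholds, kinetics, and time-course windows."""

import numpy as np
import pytest

from presynquant.io import DataError, Trace
from presynquant.minis import (
    MiniEvent,
    detect_minis,
    event_kinetics,
    mini_stats,
    mini_timecourse,
)
from presynquant.simulate import SynapseModel, psc_kernel, simulate_mini_trace


def _noise_trace(rng, sigma=1.0, duration=30.0, dt=1e-4):
    return Trace(samples=rng.normal(0.0, sigma, int(duration / dt)), dt=dt)


class TestDetection:
    def test_pure_noise_yields_no_events(self, rng):
        trace = _noise_trace(rng, sigma=1.0)
        assert detect_minis(trace, amp_threshold=8.0) == []

    def test_injected_events_recovered_with_onset_accuracy(self):
        model = SynapseModel(
            mini_rate=0.1, mini_rate_ca_slope=0.0, q_mean=20.0, q_cv=0.0,
            noise_sd=2.0, seed=11,
        )
        trace, truth = simulate_mini_trace(model, duration=100.0)
        events = detect_minis(trace)
        det_onsets = np.array([e.onset_t for e in events])
        for t_true in truth.t:
            err = np.min(np.abs(det_onsets - t_true))
            assert err < 1e-3, f"onset error {err*1e3:.2f} ms"
        assert len(events) == len(truth)

    def test_frequency_is_count_over_duration(self):
        events = [
            MiniEvent(onset_t=t, peak_t=t + 1e-3, amplitude=20.0, area=100.0)
            for t in np.linspace(1, 119, 24)
        ]
        st = mini_stats(events, duration=120.0)
        assert st.frequency == pytest.approx(0.2)
        assert st.frequency * st.duration == st.n_events

    def test_trace_shorter_than_baseline_window_errors(self, rng):
        trace = Trace(samples=rng.normal(size=100), dt=1e-4)  # 10 ms
        with pytest.raises(DataError):
            detect_minis(trace, baseline_window=0.05)

    def test_scaling_doubles_amplitude_and_area(self):
        model = SynapseModel(
            mini_rate=0.2, mini_rate_ca_slope=0.0, q_mean=25.0, q_cv=0.0,
            noise_sd=0.5, seed=5,
        )
        trace, _ = simulate_mini_trace(model, duration=60.0)
        e1 = detect_minis(trace, amp_threshold=10.0, area_threshold=5.0)
        doubled = Trace(samples=2 * trace.samples, dt=trace.dt)
        e2 = detect_minis(doubled, amp_threshold=20.0, area_threshold=10.0)
        assert len(e1) == len(e2) > 0
        for a, b in zip(e1, e2):
            assert b.amplitude == pytest.approx(2 * a.amplitude, rel=1e-9)
            assert b.area == pytest.approx(2 * a.area, rel=1e-9)

    def test_baseline_offset_invariance(self):
        model = SynapseModel(
            mini_rate=0.2, mini_rate_ca_slope=0.0, q_mean=25.0, q_cv=0.0,
            noise_sd=0.5, seed=5,
        )
        trace, _ = simulate_mini_trace(model, duration=60.0)
        shifted = Trace(samples=trace.samples + 10.0, dt=trace.dt)
        e1 = detect_minis(trace, amp_threshold=10.0)
        e2 = detect_minis(shifted, amp_threshold=10.0)
        assert len(e1) == len(e2) > 0
        for a, b in zip(e1, e2):
            assert b.amplitude == pytest.approx(a.amplitude, rel=1e-6)


class TestKinetics:
    def test_noiseless_template_decay_tau(self):
        # bi-exponential template, rise 0.5 ms / decay 5 ms: the stated
        # 90-10% single-exponential decay fit carries a small (<1%) bias
        # from the residual rising component
        dt = 1e-4
        kernel = psc_kernel(dt, 0.5, 5.0)
        x = np.zeros(int(1.0 / dt))
        i0 = 2000
        x[i0 : i0 + kernel.size] -= 20.0 * kernel
        trace = Trace(samples=x, dt=dt)
        peak_t = (i0 + int(np.argmax(kernel))) * dt
        ev = MiniEvent(onset_t=i0 * dt, peak_t=peak_t, amplitude=20.0, area=100.0)
        out = event_kinetics(trace, ev)
        assert out.kinetics_valid
        assert out.decay_tau == pytest.approx(5.0, rel=0.01)
        assert 0.3 < out.rise_10_90 < 1.2

    def test_clipped_event_flagged_missing(self):
        dt = 1e-4
        kernel = psc_kernel(dt, 0.5, 5.0)
        n = 2100
        x = np.zeros(n)
        seg = kernel[: n - 2050]
        x[2050 : 2050 + seg.size] -= 20.0 * seg  # decay clipped by trace end
        trace = Trace(samples=x, dt=dt)
        ev = MiniEvent(onset_t=0.205, peak_t=0.205 + np.argmax(kernel) * dt,
                       amplitude=20.0, area=100.0)
        out = event_kinetics(trace, ev)
        assert not out.kinetics_valid

    def test_amplitude_invariant_under_offset(self):
        dt = 1e-4
        kernel = psc_kernel(dt, 0.5, 5.0)
        x = np.zeros(10000)
        x[2000 : 2000 + kernel.size] -= 20.0 * kernel
        for offset in (0.0, 10.0):
            trace = Trace(samples=x + offset, dt=dt)
            events = detect_minis(trace, amp_threshold=10.0)
            assert len(events) == 1
            assert events[0].amplitude == pytest.approx(20.0, rel=0.02)


class TestTimecourse:
    WINDOWS = [(0.0, 120.0), (120.0, 420.0), (420.0, 720.0), (720.0, 1020.0)]

    @staticmethod
    def _poisson_events(rng, rate, t0, t1):
        n = rng.poisson(rate * (t1 - t0))
        return [
            MiniEvent(onset_t=t, peak_t=t + 1e-3, amplitude=20.0, area=100.0)
            for t in np.sort(rng.uniform(t0, t1, n))
        ]

    def test_windows_cover_baseline_plus_three_5min(self):
        spans = [t1 - t0 for t0, t1 in self.WINDOWS]
        assert spans == [120.0, 300.0, 300.0, 300.0]

    def test_stationary_rate_normalises_to_one(self, rng):
        events = self._poisson_events(rng, 2.0, 0.0, 1020.0)
        df = mini_timecourse(events, self.WINDOWS)
        assert np.allclose(df["frequency_norm"], 1.0, atol=0.25)

    def test_rate_drop_halves_normalised_frequency(self, rng):
        events = self._poisson_events(rng, 2.0, 0.0, 120.0) + self._poisson_events(
            rng, 1.0, 120.0, 1020.0
        )
        df = mini_timecourse(events, self.WINDOWS)
        assert np.allclose(df["frequency_norm"][1:], 0.5, atol=0.15)
        assert df["frequency_norm"][0] == pytest.approx(1.0)

    def test_empty_first_window_flagged(self):
        events = [
            MiniEvent(onset_t=200.0, peak_t=200.001, amplitude=20.0, area=100.0)
        ]
        with pytest.warns(UserWarning, match="first window empty"):
            df = mini_timecourse(events, self.WINDOWS)
        assert df["frequency_norm"].isna().all()

    def test_overlapping_windows_rejected(self):
        with pytest.raises(DataError):
            mini_timecourse([], [(0.0, 10.0), (5.0, 15.0)])
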
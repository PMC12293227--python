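import numpy as np
import pytest

from calmod import fluor
from calmod.errors import (
    ContractError,
    MissingNeuropilError,
    NonPositiveBaselineError,
)
from calmod.fluor import CalciumEvent, DffTrace, RoiTrace

import oracles

FS = 10.0


def make_trace(F, compartment="AS", F_np=None, **kw):
    return RoiTrace(
        roi_id=kw.pop("roi_id", "r0"),
        compartment=compartment,
        F=np.asarray(F, dtype=float),
        F_np=F_np,
        sampling_rate=FS,
        **kw,
    )


def make_dff(x, sigma=None, compartment="AS"):
    return DffTrace(
        roi_id="r0", compartment=compartment, dff=np.asarray(x, dtype=float),
        f0=100.0, sampling_rate=FS, sigma=sigma,
    )


class TestDetrend:
    def test_exact_line_removed_leaving_mean(self):
        t = np.arange(200)
        trace = make_trace(100 + 0.5 * t)
        for method in ("ols", "baseline"):
            out = fluor.detrend_linear(trace, method=method)
            assert np.allclose(out.F, trace.F.mean())
            assert np.isclose(out.F.mean(), trace.F.mean())

    def test_trend_free_trace_unchanged_under_ols(self):
        # symmetric trace: zero OLS slope, so subtraction is a no-op
        x = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)]) + 5
        trace = make_trace(x)
        out = fluor.detrend_linear(trace, method="ols")
        assert np.allclose(out.F, trace.F)

    def test_line_plus_sine_leaves_sine_with_zero_refit_slope(self, rng):
        t = np.arange(3000, dtype=float)
        sine = np.sin(2 * np.pi * t / 100)
        trace = make_trace(50 + 0.01 * t + sine)
        out = fluor.detrend_linear(trace, method="ols")
        refit = np.polyfit(t, out.F, 1)[0]
        assert abs(refit) < 1e-12
        # the discrete sine has a tiny OLS slope of its own, so the residual
        # matches the sine up to that shallow tilt
        assert np.allclose(out.F - out.F.mean(), sine - sine.mean(), atol=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(ContractError):
            fluor.detrend_linear(make_trace([1.0]))

    def test_baseline_method_ignores_transient_mass(self):
        # heavy one-sided transient load biases the OLS slope but not the
        # baseline-percentile slope
        n = 3000
        t = np.arange(n, dtype=float)
        F = np.full(n, 100.0) - 0.006 * t      # bleaching
        for onset in range(1500, 2800, 150):   # transients only in second half
            dur = 100
            F[onset:onset + dur] += 80 * np.exp(-np.arange(dur) / 30)
        out = fluor.detrend_linear(make_trace(F), method="baseline")
        # quiet-period floor should be level after detrending
        floor_first = np.percentile(out.F[:1000], 10)
        floor_last = np.percentile(out.F[-1000:], 10)
        assert abs(floor_first - floor_last) < 1.0


class TestNeuropil:
    def test_stated_arithmetic(self):
        trace = make_trace(
            np.full(50, 1.7), compartment="Neuron", F_np=np.full(50, 1.0)
        )
        out = fluor.subtract_neuropil(trace, alpha=0.7)
        assert np.allclose(out.F, 1.0)

    @pytest.mark.parametrize("alpha,np_val", [(0.7, 0.0), (0.0, 5.0)])
    def test_identity_cases(self, alpha, np_val):
        trace = make_trace(
            np.full(50, 2.0), compartment="Neuron", F_np=np.full(50, np_val)
        )
        out = fluor.subtract_neuropil(trace, alpha=alpha)
        assert np.allclose(out.F, trace.F)

    def test_astrocyte_passthrough(self):
        trace = make_trace(np.full(50, 2.0), compartment="Gp")
        assert fluor.subtract_neuropil(trace) is trace

    def test_neuron_without_neuropil_rejected(self):
        trace = make_trace(np.full(50, 2.0), compartment="Neuron")
        with pytest.raises(MissingNeuropilError):
            fluor.subtract_neuropil(trace)


class TestDff:
    def test_constant_trace_gives_zero_dff(self):
        d = fluor.compute_dff(make_trace(np.full(200, 100.0)))
        assert np.isclose(d.f0, 100.0)
        assert np.allclose(d.dff, 0.0)

    def test_plateau_trace_baseline_and_plateau_level(self):
        F = np.full(1000, 100.0)
        F[500:600] = 200.0   # contiguous 10% plateau
        d = fluor.compute_dff(make_trace(F))
        assert abs(d.f0 - 100.0) < 2.0
        assert abs(d.dff[540:560].mean() - 1.0) < 0.05

    def test_scale_invariance(self, rng):
        F = 100 + rng.normal(0, 3, 600).cumsum() * 0.01 + rng.normal(0, 1, 600)
        F = np.abs(F) + 50
        d1 = fluor.compute_dff(make_trace(F))
        d2 = fluor.compute_dff(make_trace(3.7 * F))
        assert np.allclose(d1.dff, d2.dff, atol=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(NonPositiveBaselineError):
            fluor.compute_dff(make_trace(np.full(200, -5.0)))

    def test_window_is_odd_samples_near_5s(self):
        d = fluor.compute_dff(make_trace(np.full(200, 100.0)))
        assert d.params["smooth_window_s"] == 5.0


class TestSigma:
    def test_zero_trace(self):
        assert fluor.estimate_sigma(make_dff(np.zeros(100))) == 0.0

    def test_least_noisy_window_found(self, rng):
        x = np.concatenate([rng.normal(0, 0.01, 50), rng.normal(0, 0.1, 250)])
        sig = fluor.estimate_sigma(make_dff(x))
        assert sig == pytest.approx(oracles.oracle_sigma(x, FS), abs=0)
        assert sig < 0.02

    def test_offset_invariance(self, rng):
        x = rng.normal(0, 0.05, 200)
        assert fluor.estimate_sigma(make_dff(x)) == pytest.approx(
            fluor.estimate_sigma(make_dff(x + 3.3)), abs=1e-12
        )

    def test_short_trace_rejected(self):
        with pytest.raises(ContractError):
            fluor.estimate_sigma(make_dff(np.zeros(10)))


def transient(n, onset, amp, tau_samples):
    x = np.zeros(n)
    j = np.arange(n - onset)
    x[onset:] += amp * np.exp(-j / tau_samples)
    return x


class TestDetectEvents:
    def test_subthreshold_noise_empty(self, rng):
        x = rng.normal(0, 0.01, 600)
        d = fluor.with_sigma(make_dff(x))
        assert fluor.detect_events(d) == []

    def test_single_transient_span_onset_amplitude(self):
        x = transient(600, 100, 1.0, 20)
        x[:100] = -0.001          # strictly negative baseline -> clean crossing
        x[450:] = -0.001
        d = make_dff(x, sigma=0.05)
        events = fluor.detect_events(d)
        assert len(events) == 1
        ev = events[0]
        assert ev.start_time == 10.0
        assert ev.onset_time == 10.0
        assert ev.end_time == 45.0
        assert ev.amplitude == x.max()

    def test_merged_vs_separate_lobes(self):
        # two suprathreshold bumps connected by a positive subthreshold gap
        x = np.full(400, -0.001)
        x[100:120] = 1.0
        x[120:140] = 0.02          # positive but subthreshold
        x[140:160] = 0.8
        d = make_dff(x, sigma=0.05)
        merged = fluor.detect_events(d)
        assert len(merged) == 1
        assert merged[0].amplitude == 1.0
        # the same bumps separated by a strictly negative dip
        x2 = x.copy()
        x2[120:140] = -0.02
        events = fluor.detect_events(make_dff(x2, sigma=0.05))
        assert len(events) == 2
        assert [ev.amplitude for ev in events] == [1.0, 0.8]

    def test_trace_ends_act_as_crossings(self):
        x = np.full(100, 0.5)
        events = fluor.detect_events(make_dff(x, sigma=0.05))
        assert len(events) == 1
        assert events[0].start_time == 0.0
        assert events[0].end_time == 10.0

    def test_zero_sigma_falls_back_to_floor_with_warning(self):
        x = transient(300, 50, 1.0, 10)
        d = make_dff(x, sigma=0.0)
        with pytest.warns(RuntimeWarning, match="sigma is 0"):
            events = fluor.detect_events(d)
        assert len(events) == 1

    def test_max_duration_guard_truncates(self):
        x = transient(600, 100, 1.0, 50)
        events = fluor.detect_events(make_dff(x, sigma=0.05), max_duration_s=5.0)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(5.0)

    def test_events_disjoint_sorted_and_suprathreshold(self, rng):
        x = rng.normal(0, 0.05, 2000)
        for onset in (100, 500, 900, 1400):
            x += transient(2000, onset, 0.8, 15)
        d = fluor.with_sigma(make_dff(x))
        events = fluor.detect_events(d)
        thr = max(2.0 * d.sigma, fluor.MIN_EVENT_AMPLITUDE)
        assert all(ev.amplitude > thr for ev in events)
        for e0, e1 in zip(events, events[1:]):
            assert e0.end_time <= e1.start_time
        # oracle equivalence on the same trace
        expected = oracles.oracle_events(x, FS, 2.0, d.sigma)
        got = [(ev.start_time, ev.onset_time, ev.end_time, ev.amplitude) for ev in events]
        assert got == [tuple(map(float, row)) for row in expected]


class TestEventSummary:
    def test_frequency_arithmetic(self, wt_result):
        # recompute one row by hand
        df = wt_result.state_summary
        seg = wt_result.segmentation
        row = df[(df.state == "Locomotion")].iloc[0]
        minutes = seg.total_time("Locomotion") / 60.0
        assert row.frequency_per_min == pytest.approx(row.n_events / minutes)

    def test_stateless_rois_emit_zero_freq_and_missing_stats(self, wt_session):
        from calmod import behavior as bh

        seg = bh.compose_segmentation([], [], duration=10.0, sampling_rate=FS)
        d = make_dff(np.zeros(100))
        df = fluor.summarize_events_by_state({"r0": []}, seg, [d])
        still = df[df.state == "Still"].iloc[0]
        assert still.frequency_per_min == 0.0
        assert np.isnan(still.amplitude_mean)
        # states absent from the session have zero time -> missing frequency
        loc = df[df.state == "Locomotion"].iloc[0]
        assert np.isnan(loc.frequency_per_min)
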
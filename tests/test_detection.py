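"""Baseline estimation and spontaneous transient detection."""

import numpy as np
import pytest

from microcal.detection import (
    DetectionParams,
    FluorescenceTrace,
    compute_rate,
    detect_transients,
    fit_baseline,
    read_traces_csv,
    extract_traces_from_stack,
)
from microcal.synthetic import (
    TraceSimParams,
    generate_trace,
    match_events,
    recovery_metrics,
    write_trace_csv,
)


def soma_trace(values, rate_hz=1.0, **kw):
    return FluorescenceTrace("t", "soma", np.asarray(values, float), rate_hz, **kw)


class TestBaseline:
    def test_constant_trace_baseline_exact(self):
        model = fit_baseline(soma_trace(np.full(300, 100.0)))
        assert np.allclose(model.baseline_values, 100.0)
        assert np.allclose(model.dff, 0.0)
        assert model.baseline_sd == 0.0

    def test_tracks_slow_sinusoidal_drift_within_1pct(self):
        t = np.arange(300)
        vals = 100.0 * (1.0 + 0.1 * np.sin(2 * np.pi * t / 300.0))
        model = fit_baseline(soma_trace(vals))
        rel_err = np.abs(model.baseline_values - vals) / vals
        assert rel_err.max() < 0.01

    def test_event_frames_excluded_from_fit(self):
        # a tall transient must not drag the baseline up: compare against
        # the fit on the event-free copy of the same trace
        flat = np.full(300, 100.0)
        with_event = flat.copy()
        with_event[100:110] = 100.0 * (1.0 + np.linspace(1.0, 0.1, 10))
        ref = fit_baseline(soma_trace(flat)).baseline_values
        got = fit_baseline(soma_trace(with_event)).baseline_values
        assert np.max(np.abs(got[100:110] - ref[100:110]) / ref[100:110]) < 0.01

    def test_all_frames_excluded_falls_back_to_median(self):
        # alternate frames far apart: no configuration satisfies dff < 0.10
        vals = np.where(np.arange(300) % 2 == 0, 100.0, 300.0)
        model = fit_baseline(soma_trace(vals), DetectionParams(
            baseline_dff_cutoff=1e-6, max_baseline_iterations=3))
        if model.used_fallback:
            assert np.allclose(model.baseline_values, np.median(vals))
        # either way the model must be finite and complete
        assert np.all(np.isfinite(model.baseline_values))


class TestDetection:
    def test_constant_trace_has_no_events(self):
        act = detect_transients(soma_trace(np.full(300, 100.0)))
        assert act.events == []
        assert act.rate_per_min == 0.0

    def test_boxcar_event_forced_arithmetic(self):
        # F0=100, 5 frames at 150 (1 Hz): peak dff 0.5, area 0.5*5 = 2.5
        vals = np.full(300, 100.0)
        vals[100:105] = 150.0
        act = detect_transients(soma_trace(vals))
        assert len(act.events) == 1
        ev = act.events[0]
        assert ev.peak_dff == pytest.approx(0.5, abs=1e-6)
        assert ev.area == pytest.approx(2.5, abs=1e-6)
        assert (ev.onset_frame, ev.offset_frame) == (100, 104)

    def test_all_injected_events_recovered_without_false_positives(self):
        # 10 well-separated events, amplitude 10x the noise SD, 5 min at 1 Hz
        p = TraceSimParams(duration_s=300.0, event_rate_per_min=0.0,
                           noise_sd=0.02, seed=21)
        trace, _ = generate_trace(p)
        rng = np.random.default_rng(22)
        times = np.arange(10) * 28.0 + 5.0
        t = np.arange(300)
        from microcal.synthetic import _event_kernel
        sig = np.zeros(300)
        for t0 in times:
            sig += 0.2 * _event_kernel(t - t0, p.tau_rise_s, p.tau_decay_s)
        vals = trace.values + p.f0 * sig
        act = detect_transients(soma_trace(vals))
        det = np.array([e.onset_frame for e in act.events], float)
        pairs, unmatched_true, unmatched_det = match_events(
            times, det, 1.0, tol_frames=2)
        assert len(pairs) == 10
        assert unmatched_true == []
        assert unmatched_det == []

    def test_veto_list_removes_events(self):
        vals = np.full(300, 100.0)
        vals[100:105] = 150.0
        vals[200:205] = 150.0
        tr = soma_trace(vals)
        assert len(detect_transients(tr).events) == 2
        peak = detect_transients(tr).events[0].peak_frame
        tr_vetoed = soma_trace(vals, veto_frames=(peak,))
        assert len(detect_transients(tr_vetoed).events) == 1

    def test_subthreshold_area_rejected(self):
        # 1-frame excursion of dff 0.12: area 0.12 <= 0.15 -> discarded
        vals = np.full(300, 100.0)
        vals[150] = 112.0
        act = detect_transients(soma_trace(vals))
        assert act.events == []

    def test_every_event_satisfies_both_thresholds(self):
        params = DetectionParams()
        for seed in range(10):
            trace, _ = generate_trace(TraceSimParams(
                event_rate_per_min=1.0, noise_sd=0.02, seed=seed))
            act = detect_transients(trace, params)
            thr = params.sd_multiplier * act.baseline.baseline_sd
            for ev in act.events:
                assert ev.peak_dff > thr
                assert ev.area > params.min_area

    def test_scale_invariance_of_dff_and_events(self):
        trace, _ = generate_trace(TraceSimParams(
            event_rate_per_min=0.6, noise_sd=0.02, seed=33))
        a = detect_transients(trace)
        scaled = soma_trace(trace.values * 37.5)
        b = detect_transients(scaled)
        assert len(a.events) == len(b.events)
        for ea, eb in zip(a.events, b.events):
            assert ea.onset_frame == eb.onset_frame
            assert ea.peak_dff == pytest.approx(eb.peak_dff, rel=1e-9)
            assert ea.area == pytest.approx(eb.area, rel=1e-9)

    def test_slow_drift_does_not_change_event_count(self):
        for seed in range(10):
            flat = TraceSimParams(event_rate_per_min=0.4, noise_sd=0.0,
                                  drift_amplitude=0.0, seed=seed)
            drift = TraceSimParams(event_rate_per_min=0.4, noise_sd=0.0,
                                   drift_amplitude=0.2, drift_period_s=500.0,
                                   seed=seed)
            n0 = len(detect_transients(generate_trace(flat)[0]).events)
            n1 = len(detect_transients(generate_trace(drift)[0]).events)
            assert n0 == n1

    def test_time_reversed_trace_same_event_count(self):
        for seed in range(5):
            trace, _ = generate_trace(TraceSimParams(
                event_rate_per_min=0.6, noise_sd=0.02, seed=seed))
            fwd = detect_transients(trace)
            rev = detect_transients(soma_trace(trace.values[::-1]))
            assert len(fwd.events) == len(rev.events)

    def test_recovery_metrics_on_synthetic_trace(self):
        trace, truth = generate_trace(TraceSimParams(
            event_rate_per_min=0.5, noise_sd=0.02, amp_mean=0.3, seed=17))
        act = detect_transients(trace)
        m = recovery_metrics(truth, act, trace.rate_hz)
        assert m["matched"] + m["covered"] + m["missed"] == m["n_true"]
        assert m["false_positives"] <= m["n_detected"]


class TestRates:
    def test_rate_arithmetic(self):
        vals = np.full(300, 100.0)
        vals[50:55] = 150.0
        vals[200:205] = 150.0
        act = detect_transients(soma_trace(vals))
        assert compute_rate(act) == pytest.approx(2 / 5.0)

    def test_zero_events_zero_rate(self):
        act = detect_transients(soma_trace(np.full(300, 100.0)))
        assert compute_rate(act) == 0.0

    def test_cohort_mean_rate_recovers_truth(self):
        # 100 ROIs at a true rate of 0.5/min: mean recovered rate within
        # 3 SE of a Poisson count over 5 min
        rates = []
        for seed in range(100):
            trace, _ = generate_trace(TraceSimParams(
                event_rate_per_min=0.5, noise_sd=0.02, amp_mean=0.3,
                amp_sd=0.05, seed=4000 + seed))
            rates.append(detect_transients(trace).rate_per_min)
        se = np.sqrt(0.5 / (5.0 * 100))
        assert abs(np.mean(rates) - 0.5) < 3 * se


class TestEligibilityAndIO:
    def test_thin_process_excluded_as_filopodium(self):
        thin = FluorescenceTrace("p1", "process", np.full(10, 50.0), 1.0,
                                 process_diameter_um=0.5)
        thick = FluorescenceTrace("p2", "process", np.full(10, 50.0), 1.0,
                                  process_diameter_um=1.2)
        assert not thin.eligible
        assert thick.eligible

    def test_process_without_diameter_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceTrace("p", "process", np.full(10, 50.0), 1.0)

    def test_trace_csv_round_trip(self, tmp_path):
        traces = [soma_trace(np.linspace(100, 110, 50))]
        traces[0].roi_id = "roiA"
        path = tmp_path / "traces.csv"
        write_trace_csv(path, traces)
        back = read_traces_csv(path)
        assert len(back) == 1
        assert back[0].rate_hz == pytest.approx(1.0)
        assert np.allclose(back[0].values, traces[0].values)

    def test_stack_extraction_mean_per_label(self):
        stack = np.zeros((4, 6, 6))
        labels = np.zeros((6, 6), int)
        labels[1:3, 1:3] = 1
        stack[:, 1:3, 1:3] = np.arange(4)[:, None, None]
        out = extract_traces_from_stack(stack, labels, rate_hz=1.0)
        assert np.allclose(out[1], [0, 1, 2, 3])
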
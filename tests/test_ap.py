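"""Action-potential detection, thresholds, RMP, and per-AP metrics."""

import numpy as np
import pytest

from wormtrace import ap
from wormtrace.errors import AnalysisError, FormatError, NoInflectionError
from wormtrace.synth import SmoothAP, TriangleAP, simulate_ap_train


@pytest.fixture(scope="module")
def triangle_train():
    return simulate_ap_train(n_aps=7, template=TriangleAP(), lead_ms=2.0)


@pytest.fixture(scope="module")
def smooth_train():
    return simulate_ap_train(n_aps=5, template=SmoothAP(), dvdt_criterion=10.0)


class TestLoadTrace:
    def test_csv_round_trip(self, tmp_path):
        t = np.arange(50_000) * 1e-4
        v = -60.0 + 5 * np.sin(2 * np.pi * t)
        path = tmp_path / "trace.csv"
        np.savetxt(path, np.column_stack([t, v]), delimiter=",", header="time_s,voltage_mv", comments="")
        traces = ap.load_trace(path)
        assert len(traces) == 1
        assert traces[0].dt == pytest.approx(1e-4)
        assert len(traces[0].v) == 50_000

    def test_jittered_timebase_rejected(self, tmp_path, rng):
        t = np.arange(1000) * 1e-4 + rng.normal(0, 2e-5, 1000)
        t.sort()
        path = tmp_path / "jitter.csv"
        np.savetxt(path, np.column_stack([t, np.zeros(1000)]), delimiter=",")
        with pytest.raises(FormatError, match="nonuniform"):
            ap.load_trace(path)

    def test_save_then_load(self, tmp_path, triangle_train):
        trace, _ = triangle_train
        path = tmp_path / "train.csv"
        ap.save_trace_csv(trace, path)
        back = ap.load_trace(path)[0]
        assert back.dt == pytest.approx(trace.dt)
        assert np.allclose(back.v, trace.v)


class TestDetect:
    def test_planted_train_found(self, triangle_train):
        trace, truth = triangle_train
        peaks = ap.detect_aps(trace)
        assert len(peaks) == len(truth)
        planted = np.array([ev["peak_time_ms"] for ev in truth]) * 1e-3
        assert np.abs(peaks * trace.dt - planted).max() <= trace.dt + 1e-12

    def test_flat_trace_no_peaks(self):
        trace = ap.VoltageTrace(np.full(10_000, -60.0), dt=1e-4)
        assert len(ap.detect_aps(trace)) == 0

    def test_refractory_gap_merges_close_pair(self):
        # two spikes 2 ms apart with a 5 ms refractory rule: one detection
        trace, _ = simulate_ap_train(n_aps=1, template=TriangleAP(rise_ms=0.5, fall_ms=0.5))
        v = trace.v.copy()
        shift = int(round(2e-3 / trace.dt))
        v[shift:] = np.maximum(v[shift:], trace.v[:-shift])
        doubled = ap.VoltageTrace(v, trace.dt)
        assert len(ap.detect_aps(doubled, refractory_ms=5.0)) == 1


class TestFixedLeadThreshold:
    def test_linear_rise_worked_example(self, triangle_train):
        # rise from -40 mV to +20 mV over 5 ms; lead 2 ms puts threshold at -4 mV
        trace, _ = triangle_train
        peak = int(ap.detect_aps(trace)[0])
        tp = ap.threshold_fixed_lead(trace, peak, lead_ms=2.0)
        assert tp.v_mv == pytest.approx(-4.0, abs=1e-9)
        assert peak * trace.dt - tp.time_s == pytest.approx(2e-3)

    def test_zero_lead_warns_and_equals_peak(self, triangle_train):
        trace, _ = triangle_train
        peak = int(ap.detect_aps(trace)[0])
        with pytest.warns(UserWarning):
            tp = ap.threshold_fixed_lead(trace, peak, lead_ms=0.0)
        assert tp.v_mv == trace.v[peak]

    def test_lead_beyond_trace_start_rejected(self, triangle_train):
        trace, _ = triangle_train
        peak = int(ap.detect_aps(trace)[0])
        with pytest.raises(AnalysisError):
            ap.threshold_fixed_lead(trace, peak, lead_ms=1e6)

    def test_identical_templates_identical_thresholds(self, triangle_train):
        trace, _ = triangle_train
        vs = [ap.threshold_fixed_lead(trace, int(p), 2.0).v_mv for p in ap.detect_aps(trace)]
        assert max(vs) - min(vs) <= 0.5


class TestInflectionThreshold:
    def test_recovers_analytic_takeoff(self, smooth_train):
        trace, truth = smooth_train
        peaks = ap.detect_aps(trace)
        for peak, ev in zip(peaks, truth):
            tp = ap.threshold_inflection(trace, int(peak), 10.0)
            assert tp.v_mv == pytest.approx(ev["threshold_v"], abs=2.0)
            assert tp.time_s * 1e3 == pytest.approx(ev["threshold_time_ms"], abs=0.15)

    def test_slow_ramp_has_no_inflection(self):
        v = np.full(20_000, -60.0)
        ramp = np.arange(5000) * 1e-4 * 5.0  # 5 mV/ms, below the 10 mV/ms criterion
        v[10_000:15_000] += ramp
        trace = ap.VoltageTrace(v, dt=1e-4)
        with pytest.raises(NoInflectionError):
            ap.threshold_inflection(trace, 14_999, 10.0)

    def test_threshold_rises_with_criterion(self, smooth_train):
        trace, _ = smooth_train
        for peak in ap.detect_aps(trace):
            v10 = ap.threshold_inflection(trace, int(peak), 10.0).v_mv
            v20 = ap.threshold_inflection(trace, int(peak), 20.0).v_mv
            assert v20 > v10


class TestRmp:
    def test_constant_baseline_both_modes(self):
        v = np.full(10_000, -60.0)
        trace = ap.VoltageTrace(v, dt=1e-4)
        assert ap.rmp(trace, 0.5, "fixed-lead") == pytest.approx(-60.0)
        assert ap.rmp(trace, 0.5, "inflection") == pytest.approx(-60.0)

    def test_linear_ramp_mean(self):
        # ramp of slope s ending at ref: window mean sits s*10 ms below V(ref)
        s = 0.2  # mV/ms
        t_ms = np.arange(10_000) * 0.1
        trace = ap.VoltageTrace(-70.0 + s * t_ms, dt=1e-4)
        got = ap.rmp(trace, ref_time_s=0.8, mode="fixed-lead")
        v_ref = -70.0 + s * 800.0
        assert got == pytest.approx(v_ref - s * 10.0, abs=s * 0.2)

    def test_dip_found_by_sliding_subwindow(self, rng):
        v = np.full(10_000, -60.0)
        v[7_800:7_830] = -70.0  # 3 ms dip inside the 20 ms window before ref
        v += rng.normal(0, 0.3, v.shape)
        trace = ap.VoltageTrace(v, dt=1e-4)
        ref = 0.79 + 0.01 + 0.003  # window [783 ms - 3, ...]; keep dip inside
        got_inf = ap.rmp(trace, 0.8, "inflection")
        got_fix = ap.rmp(trace, 0.8, "fixed-lead")
        assert got_inf < got_fix
        # brute force: minimum over every 3 ms sub-window mean
        ref_idx, n_w, n_s = 8000, 200, 30
        window = trace.v[ref_idx - n_w : ref_idx]
        brute = min(window[j : j + n_s].mean() for j in range(n_w - n_s + 1))
        assert got_inf == pytest.approx(brute, abs=1e-12)

    def test_truncated_window_advises_manual_measurement(self):
        trace = ap.VoltageTrace(np.full(100, -60.0), dt=1e-4)
        with pytest.raises(AnalysisError, match="manually"):
            ap.rmp(trace, 0.005, "fixed-lead")

    def test_inflection_rmp_never_above_fixed_lead(self, smooth_train):
        trace, _ = smooth_train
        for peak in ap.detect_aps(trace):
            tp = ap.threshold_inflection(trace, int(peak), 10.0)
            assert ap.rmp(trace, tp.time_s, "inflection") <= ap.rmp(
                trace, tp.time_s, "fixed-lead"
            )


class TestApMetrics:
    def test_triangle_closed_forms(self, triangle_train):
        trace, truth = triangle_train
        peak = int(ap.detect_aps(trace)[0])
        tp = ap.threshold_fixed_lead(trace, peak, 2.0)
        ev = ap.ap_metrics(trace, peak, tp, rmp_mv=-40.0)
        assert ev.amplitude_mv == pytest.approx(24.0, abs=1e-9)
        assert ev.apd50_ms == pytest.approx(3.0, abs=1e-6)
        assert ev.rise_time_ms == pytest.approx(2.0, abs=1e-9)
        assert ev.decay_time_ms == pytest.approx(4.0, abs=1e-6)
        assert ev.max_slope_mv_per_ms == pytest.approx(12.0, abs=0.01)
        assert ev.min_slope_mv_per_ms == pytest.approx(-6.0, abs=0.01)

    def test_planted_ahp_recovered(self):
        trace, truth = simulate_ap_train(
            n_aps=3, template=TriangleAP(ahp_mv=-68.0), lead_ms=2.0
        )
        peaks = ap.detect_aps(trace)
        tp = ap.threshold_fixed_lead(trace, int(peaks[0]), 2.0)
        ev = ap.ap_metrics(trace, int(peaks[0]), tp, rmp_mv=-40.0)
        assert ev.ahp_v_mv == pytest.approx(-68.0, abs=0.5)

    def test_plateau_never_recrossing_threshold(self):
        # rises, then sits on a plateau above the threshold voltage
        v = np.full(30_000, -40.0)
        rise = np.linspace(-40.0, 20.0, 51)
        v[10_000:10_051] = rise
        v[10_051:] = 5.0  # plateau above threshold (-4 mV), below half? no: above
        trace = ap.VoltageTrace(v, dt=1e-4)
        peak = 10_050
        tp = ap.threshold_fixed_lead(trace, peak, 2.0)
        ev = ap.ap_metrics(trace, peak, tp, rmp_mv=-40.0)
        assert ev.decay_time_ms is None and ev.ahp_v_mv is None

    def test_offset_invariance(self, triangle_train):
        trace, _ = triangle_train
        shifted = ap.VoltageTrace(trace.v + 17.0, trace.dt)
        for tr, off in ((trace, 0.0), (shifted, 17.0)):
            peak = int(ap.detect_aps(tr, min_peak_v_mv=-20.0 + off)[0])
            tp = ap.threshold_fixed_lead(tr, peak, 2.0)
            ev = ap.ap_metrics(tr, peak, tp, rmp_mv=-40.0 + off)
            if off == 0.0:
                base = ev
            else:
                assert ev.amplitude_mv == pytest.approx(base.amplitude_mv)
                assert ev.apd50_ms == pytest.approx(base.apd50_ms)
                assert ev.threshold_v_mv == pytest.approx(base.threshold_v_mv + off)
                assert ev.ahp_v_mv == pytest.approx(base.ahp_v_mv + off)

    def test_smooth_template_planted_parameters(self, smooth_train):
        trace, truth = smooth_train
        peaks = ap.detect_aps(trace)
        events = ap.analyze_trace(trace, method="inflection")
        assert len(events) == len(truth)
        dt_ms = trace.dt * 1e3
        for ev, exp in zip(events, truth):
            assert ev.threshold_time_s * 1e3 == pytest.approx(
                exp["threshold_time_ms"], abs=dt_ms + 1e-9
            )
            assert ev.amplitude_mv == pytest.approx(exp["amplitude"], abs=1.5)
            assert ev.apd50_ms == pytest.approx(exp["apd50_ms"], abs=dt_ms)
            assert ev.ahp_v_mv == pytest.approx(exp["ahp_v"], abs=0.5)
            assert ev.min_slope_mv_per_ms == pytest.approx(exp["min_slope"], rel=0.02)


class TestPhasePlot:
    def test_triangle_slopes(self, triangle_train):
        trace, _ = triangle_train
        peak = int(ap.detect_aps(trace)[0])
        pp = ap.phase_plot(trace, peak)
        assert pp.max_slope_mv_per_ms == pytest.approx(12.0, abs=0.01)
        assert pp.min_slope_mv_per_ms == pytest.approx(-6.0, abs=0.01)

    def test_sinusoid_peak_slope(self):
        f, amp = 5.0, 20.0
        t = np.arange(0, 1.0, 1e-4)
        trace = ap.VoltageTrace(amp * np.sin(2 * np.pi * f * t), dt=1e-4)
        pp = ap.phase_plot(trace, len(t) // 2, pre_ms=400, post_ms=400)
        assert pp.max_slope_mv_per_ms == pytest.approx(2 * np.pi * f * amp / 1e3, rel=0.02)

    def test_max_slope_between_threshold_and_peak(self, smooth_train):
        trace, _ = smooth_train
        for peak in ap.detect_aps(trace):
            tp = ap.threshold_inflection(trace, int(peak), 10.0)
            pp = ap.phase_plot(trace, int(peak), pre_ms=10, post_ms=10)
            at = int(np.argmax(pp.dvdt_mv_per_ms))
            v_at_max = pp.v_mv[at]
            assert tp.v_mv <= v_at_max <= trace.v[peak]


class TestAverageAp:
    def test_identical_templates_average_exactly(self, triangle_train):
        trace, _ = triangle_train
        peaks = ap.detect_aps(trace)
        t_rel, mean_v, n = ap.average_ap(trace, peaks)
        p0 = int(peaks[0])
        n_pre = int(round(10e-3 / trace.dt))
        n_post = int(round(20e-3 / trace.dt))
        window = trace.v[p0 - n_pre : p0 + n_post + 1]
        assert n == len(peaks)
        assert np.abs(mean_v - window).max() <= 1e-9

    def test_noise_averages_down(self):
        sigma = 2.0
        trace, truth = simulate_ap_train(n_aps=50, interval_ms=60.0, noise_sigma_mv=sigma, seed=9)
        # align on the planted peak times so only the zero-mean noise remains
        peaks = np.array([int(round(ev["peak_time_ms"] * 1e-3 / trace.dt)) for ev in truth])
        clean, truth1 = simulate_ap_train(n_aps=1, interval_ms=60.0, noise_sigma_mv=0.0)
        p1 = int(round(truth1[0]["peak_time_ms"] * 1e-3 / clean.dt))
        _, mean_v, n = ap.average_ap(trace, peaks, pre_ms=5, post_ms=10)
        n_pre, n_post = int(round(5e-3 / trace.dt)), int(round(10e-3 / trace.dt))
        template = clean.v[p1 - n_pre : p1 + n_post + 1]
        assert n == 50
        assert np.abs(mean_v - template).max() <= 3 * sigma / np.sqrt(n)

    def test_single_ap_is_its_own_average(self, triangle_train):
        trace, _ = triangle_train
        peak = ap.detect_aps(trace)[:1]
        _, mean_v, n = ap.average_ap(trace, peak)
        assert n == 1

    def test_no_fitting_window_rejected(self, triangle_train):
        trace, _ = triangle_train
        with pytest.raises(AnalysisError):
            ap.average_ap(trace, np.array([1]), pre_ms=50.0)
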
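import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ktrq import AcquisitionSchedule, AnalysisWindows, TraceSet
from ktrq.responder import (auc_12h, call_responder, call_responders,
                            classify_response_class, fit_dose_response,
                            max_amplitude, normalize_traces,
                            responder_fraction, wilson_interval)
from ktrq.synth import SimParams, class_shape, simulate_trace_ensemble


def single_trace(values, schedule, cell_id=1, valid=None):
    values = np.asarray(values, dtype=float)
    ts = TraceSet.from_matrix(values[None, :], schedule,
                              valid=None if valid is None
                              else np.asarray(valid)[None, :],
                              cell_ids=np.array([cell_id]))
    return ts.data


@pytest.fixture(scope="module")
def sched12():
    """12-min frames so pre/post windows hold exactly 5 frames each."""
    return AcquisitionSchedule(frame_interval=12, baseline_duration=240,
                               post_duration=900, meki_duration=96,
                               meki_window=24)


class TestNormalize:
    def test_constant_trace_divide_gives_ones(self, schedule):
        ts = TraceSet.from_matrix(np.full((1, schedule.n_frames), 3.7),
                                  schedule)
        out = normalize_traces(ts, mode="divide")
        assert np.allclose(out.to_matrix()[1], 1.0)

    def test_two_level_trace_subtract(self, schedule):
        vals = np.full(schedule.n_frames, 2.0)
        vals[schedule.meki_window_frames()] = 1.0
        ts = TraceSet.from_matrix(vals[None], schedule)
        out = normalize_traces(ts, mode="subtract").to_matrix()[1][0]
        assert np.allclose(vals - 1.0, out)

    def test_meki_window_maps_exactly_to_reference(self, noiseless_class3):
        traces, _ = noiseless_class3
        win = traces.schedule.meki_window_frames()
        div = normalize_traces(traces, "divide").to_matrix()[1]
        assert np.allclose(div[:, win].mean(axis=1), 1.0, atol=1e-12)
        sub = normalize_traces(traces, "subtract").to_matrix()[1]
        assert np.allclose(sub[:, win].mean(axis=1), 0.0, atol=1e-12)

    def test_nonpositive_floor_drops_cell_with_warning(self, schedule):
        good = np.full(schedule.n_frames, 2.0)
        bad = np.full(schedule.n_frames, 2.0)
        bad[schedule.meki_window_frames()] = -1.0
        ts = TraceSet.from_matrix(np.stack([good, bad]), schedule)
        with pytest.warns(UserWarning, match="dropped 1"):
            out = normalize_traces(ts, mode="divide")
        assert out.n_cells == 1


class TestCallResponder:
    def test_identical_pre_post_is_non_responder(self, sched12):
        trace = single_trace(np.full(sched12.n_frames, 1.0), sched12)
        call = call_responder(trace, sched12)
        assert not call.is_responder
        assert call.p_value == 1.0  # zero-variance differences

    def test_p_value_matches_t_distribution_oracle(self, sched12):
        d = np.array([1.0, 1.1, 0.9, 1.0, 1.0])
        vals = np.full(sched12.n_frames, 1.0)
        t = sched12.times
        post = np.nonzero((t > 240) & (t <= 300))[0]
        assert len(post) == 5
        vals[post] = 1.0 + d
        call = call_responder(single_trace(vals, sched12), sched12)
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df=4)
        assert t_oracle == pytest.approx(31.62, abs=0.01)
        assert call.p_value == pytest.approx(p_oracle, rel=1e-10)
        assert call.is_responder
        assert call.direction == "increase"

    def test_decrease_only_counts_under_any_policy(self, sched12):
        rng = np.random.default_rng(0)
        vals = np.full(sched12.n_frames, 2.0) + rng.normal(0, 0.01,
                                                           sched12.n_frames)
        t = sched12.times
        vals[t > 240] -= 1.0
        trace = single_trace(vals, sched12)
        assert not call_responder(trace, sched12, policy="increase_only"
                                  ).is_responder
        call = call_responder(trace, sched12, policy="any")
        assert call.is_responder
        assert call.direction == "decrease"

    def test_insufficient_frames_flagged_indeterminate(self, sched12):
        vals = np.full(sched12.n_frames, 1.0)
        valid = np.ones(sched12.n_frames, dtype=bool)
        t = sched12.times
        valid[(t > 180) & (t <= 240)] = False  # kill most of the pre window
        valid[t == 240] = True
        call = call_responder(single_trace(vals, sched12, valid=valid),
                              sched12)
        assert call.indeterminate

    def test_vectorized_path_matches_per_cell_path(self, schedule):
        params = SimParams(response_class=2, n_cells=40, noise_sigma=0.1,
                           seed=17, dose=30.0)
        traces, _ = simulate_trace_ensemble(params, schedule)
        norm = normalize_traces(traces)
        fast = call_responders(norm)   # fully valid -> vectorized
        slow = [call_responder(cell, schedule) for _, cell in
                norm.iter_cells()]
        for f, s in zip(fast, slow):
            assert f.cell_id == s.cell_id
            assert f.is_responder == s.is_responder
            assert f.p_value == pytest.approx(s.p_value, rel=1e-9, abs=1e-12)


class TestAmplitude:
    def test_flat_trace_zero(self, sched12):
        trace = single_trace(np.full(sched12.n_frames, 1.0), sched12)
        assert max_amplitude(trace, sched12) == 0.0

    def test_step_response(self, sched12):
        vals = np.full(sched12.n_frames, 1.0)
        vals[sched12.times > 240] = 2.5
        assert max_amplitude(single_trace(vals, sched12),
                             sched12) == pytest.approx(1.5)

    def test_window_cap_respected_for_late_peak(self, sched12):
        # ramp peaking at 90 min post-treatment: amplitude is the 60-min value
        t = sched12.times
        vals = np.full(sched12.n_frames, 1.0)
        ramp = (t > 240) & (t <= 240 + 90)
        vals[ramp] = 1.0 + (t[ramp] - 240) / 90.0
        late = t > 330
        vals[late] = 2.0
        amp = max_amplitude(single_trace(vals, sched12), sched12)
        assert amp == pytest.approx((60 / 90), abs=1e-12)


class TestAUC:
    def test_flat_trace_zero(self, sched12):
        trace = single_trace(np.full(sched12.n_frames, 1.0), sched12)
        auc, low = auc_12h(trace, sched12)
        assert auc == pytest.approx(0.0, abs=1e-12)
        assert not low

    def test_constant_elevation_rectangle(self, sched12):
        vals = np.full(sched12.n_frames, 1.0)
        vals[sched12.times > 240] = 2.0
        auc, _ = auc_12h(single_trace(vals, sched12), sched12)
        # first trapezoid spans the 1 -> 2 step: 12 h minus half a frame
        half_frame_h = sched12.frame_interval / 2 / 60
        assert auc == pytest.approx(12.0 - half_frame_h, abs=1e-9)

    def test_transient_pulse_matches_analytic_integral(self, schedule):
        # closed form: int_0^T (s/tau) e^(1-s/tau) ds
        #            = e*tau*(1 - (1 + T/tau) e^(-T/tau))
        tau = 30.0
        t = schedule.times
        vals = 1.0 + class_shape(t - 240.0, 1, tau)
        auc, _ = auc_12h(single_trace(vals, schedule), schedule)
        T = 720.0
        exact_min = np.e * tau * (1 - (1 + T / tau) * np.exp(-T / tau))
        assert auc == pytest.approx(exact_min / 60.0, rel=0.01)

    def test_auc_linear_in_amplitude(self, schedule):
        t = schedule.times
        f = class_shape(t - 240.0, 2, 12.0, 240.0)
        a1, _ = auc_12h(single_trace(1 + f, schedule), schedule)
        a2, _ = auc_12h(single_trace(1 + 2 * f, schedule), schedule)
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_invalid_frames_interpolated_and_flagged(self, schedule):
        t = schedule.times
        vals = np.full(schedule.n_frames, 1.0)
        vals[t > 240] = 2.0
        valid = np.ones(schedule.n_frames, dtype=bool)
        win = (t > 300) & (t <= 800)    # >25% of the AUC window invalid
        valid[win] = False
        auc, low = auc_12h(single_trace(vals, schedule, valid=valid),
                           schedule)
        assert low
        half_frame_h = schedule.frame_interval / 2 / 60
        assert auc == pytest.approx(12.0 - half_frame_h, abs=1e-6)


class TestFractionAndDoseResponse:
    def test_fraction_arithmetic(self):
        from ktrq.responder import ResponderCall
        calls = [ResponderCall(cell_id=i, p_value=0.5, is_responder=False)
                 for i in range(100)]
        frac, (lo, hi) = responder_fraction(calls)
        assert frac == 0.0
        calls = [ResponderCall(cell_id=i, p_value=0.001,
                               is_responder=i < 600) for i in range(1000)]
        frac, _ = responder_fraction(calls)
        assert frac == pytest.approx(0.60)

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            responder_fraction([])

    def test_wilson_interval_properties(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            lo, hi = wilson_interval(k, n)
            assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_wilson_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        for k, n in [(0, 10), (3, 17), (600, 1000), (42, 42)]:
            lo, hi = wilson_interval(k, n)
            slo, shi = proportion_confint(k, n, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_hill_parameters_recovered_from_noiseless_fractions(self):
        doses = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        truth = 0.8 / (1 + (10.0 / doses) ** 1.0)
        fit = fit_dose_response(doses, truth)
        assert fit.ec50 == pytest.approx(10.0, rel=0.15)
        assert fit.pmax == pytest.approx(0.8, rel=0.1)
        assert not fit.flags

    def test_flat_fractions_flagged_unidentifiable(self):
        fit = fit_dose_response([1, 10, 100], [0.5, 0.5, 0.5])
        assert "ec50_unidentifiable" in fit.flags
        assert fit.pmax == pytest.approx(0.5, abs=0.05)

    def test_non_monotone_data_flagged_not_fatal(self):
        fit = fit_dose_response([1, 10, 100], [0.2, 0.6, 0.4])
        assert "non_monotone" in fit.flags

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([0.0, 1.0, 10.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            fit_dose_response([1.0, 10.0], [0.1, 0.2])


class TestClassification:
    def make_ensemble(self, response_class, seed=0, n=60):
        params = SimParams(response_class=response_class, n_cells=n,
                           noise_sigma=0.1, responder_pmax=1.0,
                           responder_ec50=1e-9, seed=seed)
        traces, _ = simulate_trace_ensemble(params)
        return normalize_traces(traces)

    @pytest.mark.parametrize("cls", [1, 2, 3])
    def test_generated_class_recovered(self, cls):
        norm = self.make_ensemble(cls, seed=cls)
        assert classify_response_class(norm) == cls

    def test_too_few_responders_rejected(self):
        norm = self.make_ensemble(3, seed=9, n=25)
        # keep only 5 cells
        ids = norm.cell_ids[:5]
        small = TraceSet(norm.data[norm.data.cell_id.isin(ids)].copy(),
                         norm.schedule)
        with pytest.raises(ValueError, match="responder traces"):
            classify_response_class(small)

    def test_flat_ensemble_unclassifiable(self, schedule):
        params = SimParams(response_class=0, n_cells=30, noise_sigma=0.0,
                           seed=3)
        traces, _ = simulate_trace_ensemble(params, schedule)
        norm = normalize_traces(traces)
        with pytest.raises(ValueError):
            classify_response_class(norm, min_responders=0)


class TestNormalizationInvariance:
    def test_amplitude_and_auc_affine_map_between_modes(self, schedule):
        params = SimParams(response_class=3, n_cells=10, noise_sigma=0.0,
                           responder_pmax=1.0, responder_ec50=1e-9,
                           amplitude_cv=0.0, seed=2)
        traces, _ = simulate_trace_ensemble(params, schedule)
        div = normalize_traces(traces, "divide")
        sub = normalize_traces(traces, "subtract")
        # per cell the floor mean m links the two scales: x/m vs x - m
        _, act, valid = traces.to_matrix()
        m = act[:, schedule.meki_window_frames()].mean(axis=1)
        for (cid_d, cell_d), (cid_s, cell_s), mi in zip(
                div.iter_cells(), sub.iter_cells(), m):
            amp_d = max_amplitude(cell_d, schedule)
            amp_s = max_amplitude(cell_s, schedule)
            assert amp_d == pytest.approx(amp_s / mi, rel=1e-9)
            auc_d, _ = auc_12h(cell_d, schedule)
            auc_s, _ = auc_12h(cell_s, schedule)
            assert auc_d == pytest.approx(auc_s / mi, rel=1e-9)
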
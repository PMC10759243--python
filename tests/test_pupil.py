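"""Pupillogram preprocessing: interpolation, smoothing, averaging, baselining."""

from __future__ import annotations

import numpy as np
import pytest

from gazesa.pupil import (
    INTERPOLATED,
    MEASURED,
    MISSING,
    AlignmentError,
    PupilTrace,
    average_binocular,
    baseline_normalize,
    interpolate_gaps,
    pupillogram,
    smooth_sg,
    trace_from_recording,
)
from gazesa.simulate import ScenarioConfig, default_profiles, simulate_recording

from conftest import make_recording


def make_trace(d, dt=10.0, stage="raw"):
    d = np.asarray(d, float)
    mask = np.where(np.isfinite(d), MEASURED, MISSING)
    return PupilTrace(np.arange(len(d)) * dt, d, mask, stage=stage)


class TestInterpolateGaps:
    def test_linear_signal_recovered_exactly(self):
        t = np.arange(60) * 10.0
        d = 3.0 + 0.002 * t
        gappy = d.copy()
        gappy[20:35] = np.nan  # 15-sample interior gap
        filled = interpolate_gaps(make_trace(gappy))
        assert np.allclose(filled.d, d, atol=1e-9)
        assert (filled.mask[20:35] == INTERPOLATED).all()
        assert filled.stage == "filled"

    def test_constant_signal_filled_with_constant(self):
        d = np.full(50, 3.5)
        d[10:20] = np.nan
        filled = interpolate_gaps(make_trace(d))
        assert np.allclose(filled.d, 3.5, atol=1e-12)

    def test_quadratic_gap_matches_independent_slope_rule(self):
        # independent re-implementation of the 10+10 flanking-point rule
        t = np.arange(80) * 10.0
        d = 3.0 + 1e-6 * (t - 400.0) ** 2
        gappy = d.copy()
        gap = slice(40, 46)
        gappy[gap] = np.nan
        filled = interpolate_gaps(make_trace(gappy), half_window=10)
        before = np.arange(30, 40)
        after = np.arange(46, 56)
        flank = np.concatenate([before, after])
        tt, dd = t[flank], d[flank]
        slope = (
            np.sum((tt - tt.mean()) * (dd - dd.mean()))
            / np.sum((tt - tt.mean()) ** 2)
        )
        expected = d[39] + slope * (t[gap] - t[39])
        assert np.allclose(filled.d[gap], expected, atol=1e-9)

    def test_edge_gaps_left_missing(self):
        d = np.full(30, 3.0)
        d[:5] = np.nan
        d[-4:] = np.nan
        filled = interpolate_gaps(make_trace(d))
        assert np.isnan(filled.d[:5]).all()
        assert np.isnan(filled.d[-4:]).all()

    def test_gap_longer_than_max_left_missing(self):
        d = np.full(200, 3.0)
        d[50:150] = np.nan  # 1000 ms gap at dt=10
        filled = interpolate_gaps(make_trace(d), max_gap_ms=500.0)
        assert np.isnan(filled.d[50:150]).all()
        assert (filled.mask[50:150] == MISSING).all()

    def test_insufficient_flank_warns_and_skips(self, caplog):
        d = np.full(30, 3.0)
        d[3:8] = np.nan  # only 3 valid points before the gap
        with caplog.at_level("WARNING", logger="gazesa.pupil"):
            filled = interpolate_gaps(make_trace(d), half_window=10)
        assert np.isnan(filled.d[3:8]).all()
        assert "unfilled" in caplog.text

    def test_measured_points_never_altered(self):
        rng = np.random.default_rng(0)
        d = 3.0 + rng.normal(0, 0.1, 100)
        gappy = d.copy()
        gappy[30:40] = np.nan
        filled = interpolate_gaps(make_trace(gappy))
        keep = np.isfinite(gappy)
        assert np.array_equal(filled.d[keep], gappy[keep])


class TestSmoothSG:
    def test_constant_signal_unchanged(self):
        sm = smooth_sg(make_trace(np.full(100, 3.3), stage="filled"))
        assert np.allclose(sm.d, 3.3, atol=1e-12)

    def test_cubic_polynomial_reproduced(self):
        t = np.arange(100) * 10.0
        d = 3 + 1e-4 * t - 1e-7 * t**2 + 1e-11 * t**3
        sm = smooth_sg(make_trace(d, stage="filled"), window=21, polyorder=3)
        assert np.allclose(sm.d, d, atol=1e-9)

    def test_window5_order2_matches_closed_form_kernel(self):
        rng = np.random.default_rng(7)
        d = rng.normal(3.0, 0.2, 60)
        sm = smooth_sg(make_trace(d, stage="filled"), window=5, polyorder=2)
        kernel = np.array([-3.0, 12.0, 17.0, 12.0, -3.0]) / 35.0
        for i in range(2, 58):
            expected = float(np.dot(kernel, d[i - 2 : i + 3]))
            assert sm.d[i] == pytest.approx(expected, abs=1e-10)

    def test_missing_spans_propagate(self):
        d = np.full(100, 3.0)
        d[40:60] = np.nan
        sm = smooth_sg(make_trace(d, stage="filled"))
        assert np.isnan(sm.d[40:60]).all()
        assert (sm.mask == MISSING).sum() == 20

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth_sg(make_trace(np.full(10, 3.0), stage="filled"), window=21)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_sg(make_trace(np.full(50, 3.0), stage="filled"), window=20)


class TestAverageBinocular:
    def test_pointwise_mean(self):
        left = make_trace([3.0, 3.0], stage="smoothed")
        right = make_trace([4.0, 4.0], stage="smoothed")
        avg = average_binocular(left, right)
        assert np.allclose(avg.d, 3.5)

    def test_single_eye_fallback(self):
        left = make_trace([np.nan, 3.0], stage="smoothed")
        right = make_trace([4.0, np.nan], stage="smoothed")
        avg = average_binocular(left, right)
        assert avg.d.tolist() == [4.0, 3.0]

    def test_both_missing_stays_missing(self):
        left = make_trace([np.nan, 3.0], stage="smoothed")
        right = make_trace([np.nan, 3.0], stage="smoothed")
        avg = average_binocular(left, right)
        assert np.isnan(avg.d[0])
        assert avg.mask[0] == MISSING

    def test_random_traces_match_elementwise_oracle(self):
        rng = np.random.default_rng(11)
        dl = rng.normal(3, 0.3, 300)
        dr = rng.normal(3, 0.3, 300)
        dl[rng.random(300) < 0.2] = np.nan
        dr[rng.random(300) < 0.2] = np.nan
        avg = average_binocular(
            make_trace(dl, stage="smoothed"), make_trace(dr, stage="smoothed")
        )
        for i in range(300):
            l_ok, r_ok = np.isfinite(dl[i]), np.isfinite(dr[i])
            if l_ok and r_ok:
                assert avg.d[i] == pytest.approx((dl[i] + dr[i]) / 2)
            elif l_ok:
                assert avg.d[i] == dl[i]
            elif r_ok:
                assert avg.d[i] == dr[i]
            else:
                assert np.isnan(avg.d[i])

    def test_mismatched_time_bases_rejected(self):
        left = make_trace([3.0, 3.0], dt=10.0, stage="smoothed")
        right = make_trace([3.0, 3.0], dt=20.0, stage="smoothed")
        with pytest.raises(AlignmentError):
            average_binocular(left, right)


class TestBaselineNormalize:
    def test_constant_trace_baselines_to_zero(self):
        tr = make_trace(np.full(300, 3.5), stage="averaged")
        out = baseline_normalize(tr, (0.0, 2000.0))
        assert np.allclose(out.d, 0.0, atol=1e-12)
        assert out.stage == "normalized"

    def test_bump_over_baseline(self):
        d = np.full(400, 3.0)
        d[250:300] += 0.3
        out = baseline_normalize(make_trace(d, stage="averaged"), (0.0, 2000.0))
        assert out.d.max() == pytest.approx(0.3)
        assert out.d_norm.max() == pytest.approx(0.1)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        d = 3.0 + rng.normal(0, 0.1, 400)
        a = baseline_normalize(make_trace(d, stage="averaged"), (0.0, 2000.0))
        b = baseline_normalize(make_trace(d + 1.7, stage="averaged"), (0.0, 2000.0))
        assert np.allclose(a.d, b.d, atol=1e-12)

    def test_empty_baseline_window_rejected(self):
        tr = make_trace(np.full(100, 3.0), stage="averaged")
        with pytest.raises(ValueError, match="baseline"):
            baseline_normalize(tr, (50_000.0, 60_000.0))


class TestPupillogram:
    def test_recovers_injected_dilation_bump(self, small_scenario):
        expert, _ = default_profiles(small_scenario)
        rec, truth = simulate_recording(expert, small_scenario, seed=31)
        trace = pupillogram(rec)
        # locate the bump as the midpoint of the half-maximum region
        d = np.where(np.isfinite(trace.d), trace.d, -np.inf)
        half = d.max() / 2.0
        above = trace.t_ms[d > half]
        mid = 0.5 * (above[0] + above[-1])
        assert abs(mid - truth.dilation_peak_ms) < 1000.0
        assert trace.d.max() == pytest.approx(truth.dilation_mm, rel=0.25)

    def test_no_pupil_data_rejected(self):
        rec = make_recording(
            np.arange(100) * 10.0, np.zeros(100), np.zeros(100)
        )
        with pytest.raises(ValueError, match="pupil"):
            pupillogram(rec)

    def test_deterministic(self, expert_sim):
        rec, _ = expert_sim
        a = pupillogram(rec)
        b = pupillogram(rec)
        assert np.array_equal(a.d, b.d, equal_nan=True)
        assert a.history == b.history

    def test_stage_history_records_pipeline_order(self, expert_sim):
        rec, _ = expert_sim
        trace = pupillogram(rec)
        assert trace.history[0] == "raw"
        assert trace.history[-1] == "normalized"
        assert trace.history.index("filled") < trace.history.index("smoothed")

    def test_binocular_averaging_halves_noise_variance(self, small_scenario):
        expert, _ = default_profiles(small_scenario)
        rec, truth = simulate_recording(expert, small_scenario, seed=77)
        left = trace_from_recording(rec, "left")
        right = trace_from_recording(rec, "right")
        avg = average_binocular(left, right)
        res_l = left.d - truth.pupil_latent
        res_a = avg.d - truth.pupil_latent
        both = np.isfinite(left.d) & np.isfinite(right.d)
        ratio = np.nanvar(res_a[both]) / np.nanvar(res_l[both])
        assert ratio == pytest.approx(0.5, rel=0.15)
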
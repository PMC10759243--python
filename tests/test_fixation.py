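"""I-VT classification against a brute-force run-length oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from gazesa.fixation import (
    InsufficientDataError,
    classify_segments,
    compute_velocity,
    detect_fixations_ivt,
)

from conftest import make_recording


def ivt_oracle(t, x, y, valid, threshold, min_fix_ms, max_gap_ms):
    """Explicit run-length scan over the thresholded speed sequence.

    Independent of the package implementation: a plain Python loop over
    consecutive valid samples.
    """
    vi = [i for i in range(len(t)) if valid[i]]
    out = []

    def flush(run):
        if len(run) > 1 and t[run[-1]] - t[run[0]] >= min_fix_ms:
            out.append(
                (
                    t[run[0]],
                    t[run[-1]],
                    sum(x[i] for i in run) / len(run),
                    sum(y[i] for i in run) / len(run),
                )
            )

    if not vi:
        return out
    run = [vi[0]]
    for a, b in zip(vi, vi[1:]):
        dt = t[b] - t[a]
        speed = math.hypot(x[b] - x[a], y[b] - y[a]) / dt
        if dt <= max_gap_ms and speed < threshold:
            run.append(b)
        else:
            flush(run)
            run = [b]
    flush(run)
    return out


def random_stream(rng, n):
    """A gaze stream mixing dwells, jumps, track loss and speed ties."""
    t = np.arange(n) * 5.0
    x = np.zeros(n)
    y = np.zeros(n)
    pos = np.array([500.0, 400.0])
    i = 0
    while i < n:
        kind = rng.choice(["dwell", "jump", "drift"], p=[0.5, 0.3, 0.2])
        m = int(rng.integers(2, 40))
        m = min(m, n - i)
        if kind == "dwell":
            x[i : i + m] = pos[0] + rng.normal(0, 0.3, m)
            y[i : i + m] = pos[1] + rng.normal(0, 0.3, m)
        elif kind == "jump":
            target = rng.uniform(0, 1000, 2)
            frac = np.linspace(0, 1, m)
            x[i : i + m] = pos[0] + frac * (target[0] - pos[0])
            y[i : i + m] = pos[1] + frac * (target[1] - pos[1])
            pos = target
        else:  # drift near the threshold speed
            speed = rng.uniform(0.2, 0.7)
            angle = rng.uniform(0, 2 * np.pi)
            step = speed * 5.0
            x[i : i + m] = pos[0] + np.arange(m) * step * np.cos(angle)
            y[i : i + m] = pos[1] + np.arange(m) * step * np.sin(angle)
            pos = np.array([x[i + m - 1], y[i + m - 1]])
        i += m
    valid = rng.random(n) > 0.05
    # a few longer track-loss bursts
    for _ in range(max(1, n // 200)):
        s = int(rng.integers(0, n))
        valid[s : s + int(rng.integers(5, 40))] = False
    return t, x, y, valid


class TestComputeVelocity:
    def test_stationary_pair_has_zero_speed(self):
        rec = make_recording([0.0, 3.333], [10.0, 10.0], [20.0, 20.0])
        v = compute_velocity(rec)
        assert np.isnan(v.speed[0])
        assert v.speed[1] == 0.0

    def test_three_four_five_triangle(self):
        rec = make_recording([0.0, 10.0], [0.0, 3.0], [0.0, 4.0])
        assert compute_velocity(rec).speed[1] == pytest.approx(0.5)

    def test_undefined_over_invalid_and_long_gaps(self):
        rec = make_recording(
            [0.0, 10.0, 200.0, 210.0],
            [0.0, 1.0, 2.0, 3.0],
            [0.0] * 4,
            valid=[True, False, True, True],
        )
        v = compute_velocity(rec, max_gap_ms=75.0)
        assert np.isnan(v.speed[1])  # second sample invalid
        assert np.isnan(v.speed[2])  # gap of 190 ms > 75 ms
        assert v.speed[3] == pytest.approx(0.1)

    def test_matches_pairwise_recomputation_on_random_stream(self):
        rng = np.random.default_rng(42)
        t = np.cumsum(rng.uniform(2, 8, 100))
        x = rng.uniform(0, 1000, 100)
        y = rng.uniform(0, 1000, 100)
        rec = make_recording(t, x, y)
        v = compute_velocity(rec, max_gap_ms=1e9)
        for i in range(1, 100):
            expected = math.hypot(x[i] - x[i - 1], y[i] - y[i - 1]) / (
                t[i] - t[i - 1]
            )
            assert v.speed[i] == pytest.approx(expected)

    def test_too_few_valid_samples(self):
        rec = make_recording([0.0, 10.0], [0, 0], [0, 0], valid=[True, False])
        with pytest.raises(InsufficientDataError):
            compute_velocity(rec)


class TestDetectFixations:
    def test_stationary_recording_is_one_fixation(self):
        n = 500
        t = np.arange(n) * 10.0
        rec = make_recording(t, np.full(n, 320.0), np.full(n, 240.0))
        fx = detect_fixations_ivt(rec)
        assert len(fx) == 1
        assert fx[0].onset_ms == 0.0
        assert fx[0].offset_ms == t[-1]
        assert (fx[0].cx, fx[0].cy) == (320.0, 240.0)

    def test_two_fixations_with_one_saccade(self):
        rng = np.random.default_rng(1)
        dt = 5.0
        a = 200  # 1 s at A
        s = 6  # 30 ms saccade at 3 px/ms
        b = 200  # 1 s at B
        n = a + s + b
        t = np.arange(n) * dt
        x = np.empty(n)
        y = np.empty(n)
        x[:a] = 100 + rng.normal(0, 0.2, a)
        y[:a] = 100 + rng.normal(0, 0.2, a)
        x[a : a + s] = 100 + (np.arange(1, s + 1)) * 3.0 * dt
        y[a : a + s] = 100.0
        x[a + s :] = x[a + s - 1] + rng.normal(0, 0.2, b)
        y[a + s :] = 100 + rng.normal(0, 0.2, b)
        fx = detect_fixations_ivt(make_recording(t, x, y))
        assert len(fx) == 2
        assert fx[0].cx == pytest.approx(100, abs=1)
        assert fx[1].cx == pytest.approx(x[a + s - 1], abs=1)
        assert fx[0].index == 1 and fx[1].index == 2

    def test_speed_exactly_at_threshold_is_saccade(self):
        # 0.42 px/ms over 10 ms steps: displacement exactly 4.2 px
        t = np.arange(10) * 10.0
        x = np.arange(10) * 4.2
        fx = detect_fixations_ivt(make_recording(t, x, np.zeros(10)))
        assert fx == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 3000))
        t, x, y, valid = random_stream(rng, n)
        rec = make_recording(t, x, y, valid=valid)
        fx = detect_fixations_ivt(rec)
        expected = ivt_oracle(t, x, y, valid, 0.42, 60.0, 75.0)
        assert len(fx) == len(expected)
        for f, (onset, offset, cx, cy) in zip(fx, expected):
            assert f.onset_ms == pytest.approx(onset)
            assert f.offset_ms == pytest.approx(offset)
            assert f.cx == pytest.approx(cx)
            assert f.cy == pytest.approx(cy)

    def test_raising_threshold_never_decreases_total_duration(self):
        rng = np.random.default_rng(9)
        t, x, y, valid = random_stream(rng, 2000)
        rec = make_recording(t, x, y, valid=valid)
        totals = [
            sum(f.duration_ms for f in detect_fixations_ivt(rec, thr))
            for thr in (0.1, 0.3, 0.42, 0.8, 2.0, 10.0)
        ]
        assert totals == sorted(totals)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        t, x, y, valid = random_stream(rng, 1000)
        rec = make_recording(t, x, y, valid=valid)
        assert detect_fixations_ivt(rec) == detect_fixations_ivt(rec)

    def test_bridges_short_gap_but_not_long_gap(self):
        # stationary dwell interrupted by 50 ms of track loss: one fixation
        t = np.arange(100) * 10.0
        x = np.full(100, 50.0)
        valid = np.ones(100, bool)
        valid[40:45] = False
        fx = detect_fixations_ivt(make_recording(t, x, np.zeros(100), valid=valid))
        assert len(fx) == 1
        # 200 ms of loss exceeds max_gap_ms=75: fixation is split
        valid2 = np.ones(100, bool)
        valid2[40:60] = False
        fx2 = detect_fixations_ivt(
            make_recording(t, x, np.zeros(100), valid=valid2)
        )
        assert len(fx2) == 2


class TestSegments:
    @pytest.mark.parametrize("seed", range(4))
    def test_partition_covers_recording_span(self, seed):
        rng = np.random.default_rng(seed)
        t, x, y, valid = random_stream(rng, 1500)
        valid[0] = valid[-1] = True  # anchor span ends
        rec = make_recording(t, x, y, valid=valid)
        seg = classify_segments(rec)
        assert seg["duration_ms"].sum() == pytest.approx(t[-1] - t[0])
        # fixation segments agree with the detector's total
        fx = detect_fixations_ivt(rec)
        fix_total = seg.loc[seg["kind"] == "fixation", "duration_ms"].sum()
        assert fix_total == pytest.approx(sum(f.duration_ms for f in fx))

    def test_total_fixation_time_bounded_by_span(self, expert_sim):
        rec, _ = expert_sim
        fx = detect_fixations_ivt(rec)
        assert sum(f.duration_ms for f in fx) <= rec.duration_ms
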
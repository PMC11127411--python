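"""Oxygen-flux arithmetic, trend bucketing, session summaries, failure detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from do2mon.do2_engine import (
    DO2Frame,
    FailureReason,
    bucket_trend,
    compute_do2,
    derive_series,
    detect_failure,
    summarize_session,
)
from do2mon.sync_engine import SyncedFrame


def valid_frame(t, co, sphb, spo2):
    return SyncedFrame(t=t, co=co, sphb=sphb, spo2=spo2, valid=True)


def invalid_frame(t):
    return SyncedFrame(t=t, co=None, sphb=None, spo2=None, valid=False)


class TestComputeDO2:
    @pytest.mark.parametrize(
        "co, sphb, spo2, expected",
        [
            (0.0, 12.0, 0.99, 0.0),
            (5.0, 10.6, 1.0, 710.2),
            (4.0, 12.0, 0.98, 630.336),
        ],
    )
    def test_oxygen_flux_equation(self, co, sphb, spo2, expected):
        do2, indexed = compute_do2(co, sphb, spo2)
        assert do2 == pytest.approx(expected, rel=1e-12)
        assert indexed is None

    def test_bsa_indexing(self):
        do2, indexed = compute_do2(5.0, 10.6, 1.0, bsa_m2=2.0)
        assert indexed == pytest.approx(do2 / 2.0)

    def test_non_finite_input_yields_missing(self):
        assert compute_do2(float("nan"), 12.0, 0.99) == (None, None)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        co=st.floats(0.5, 10),
        sphb=st.floats(5, 18),
        spo2=st.floats(0.5, 1.0),
        k=st.floats(0.1, 4),
    )
    def test_linear_in_each_argument(self, co, sphb, spo2, k):
        base, _ = compute_do2(co, sphb, spo2)
        scaled, _ = compute_do2(co * k, sphb, spo2)
        assert scaled == pytest.approx(k * base, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(co=st.floats(4, 8), sphb=st.floats(10, 16), spo2=st.floats(0.95, 1.0))
    def test_physiological_range_bounds(self, co, sphb, spo2):
        do2, _ = compute_do2(co, sphb, spo2)
        assert 509.0 <= do2 <= 1716.0


class TestDeriveSeries:
    def test_constant_valid_frames(self):
        frames = [valid_frame(2.0 * i, 5.0, 10.6, 1.0) for i in range(10)]
        series = derive_series(frames)
        assert [f.t for f in series] == [f.t for f in frames]
        assert all(f.do2 == pytest.approx(710.2) for f in series)

    def test_invalid_frames_stay_missing(self):
        series = derive_series([invalid_frame(0.0), invalid_frame(2.0)])
        assert all(f.do2 is None for f in series)

    def test_empty(self):
        assert derive_series([]) == []


class TestBucketTrend:
    def test_constant_single_bucket(self):
        frames = [DO2Frame(t=2.0 * i, do2=500.0) for i in range(10)]
        points = bucket_trend(frames)
        assert len(points) == 1
        assert points[0].bucket_start_s == 0.0
        assert points[0].mean_do2 == pytest.approx(500.0)
        assert points[0].n_frames == 10

    def test_ramp_mean(self):
        frames = [DO2Frame(t=float(t), do2=float(t)) for t in range(0, 20, 2)]
        (point,) = bucket_trend(frames)
        assert point.mean_do2 == pytest.approx(9.0)

    def test_all_missing_bucket_omitted(self):
        frames = [DO2Frame(t=float(t), do2=None) for t in range(0, 20, 2)]
        assert bucket_trend(frames) == []

    def test_trend_conserves_overall_mean(self, rng):
        frames = [
            DO2Frame(t=2.0 * i, do2=None if rng.random() < 0.2 else float(rng.uniform(300, 900)))
            for i in range(200)
        ]
        points = bucket_trend(frames)
        values = [f.do2 for f in frames if f.do2 is not None]
        weighted = sum(p.mean_do2 * p.n_frames for p in points) / sum(p.n_frames for p in points)
        assert weighted == pytest.approx(np.mean(values), rel=1e-12)
        assert sum(p.n_frames for p in points) == len(values)


class TestSummarize:
    def test_constant_series(self):
        frames = [DO2Frame(t=2.0 * i, do2=500.0) for i in range(100)]
        s = summarize_session(frames, grid_step_s=2.0)
        assert s.mean_do2 == pytest.approx(500.0)
        assert s.p10_do2 == pytest.approx(500.0)
        assert s.valid_duration_min == pytest.approx(100 * 2 / 60)
        assert not s.failed

    def test_decile_by_linear_interpolation(self):
        # sorted values 100..1000: rank h = (10-1)*0.1 + 1 = 1.9 -> 190
        frames = [DO2Frame(t=2.0 * i, do2=100.0 * (i + 1)) for i in range(10)]
        s = summarize_session(frames)
        assert s.p10_do2 == pytest.approx(190.0)
        assert s.mean_do2 == pytest.approx(550.0)

    def test_stats_bounded_by_extremes(self, rng):
        values = rng.uniform(200, 900, size=37)
        frames = [DO2Frame(t=2.0 * i, do2=float(v)) for i, v in enumerate(values)]
        s = summarize_session(frames)
        assert values.min() <= s.p10_do2 <= values.max()
        assert values.min() <= s.mean_do2 <= values.max()

    def test_empty_session_is_failed_with_missing_stats(self):
        s = summarize_session([])
        assert s.failed and s.mean_do2 is None and s.p10_do2 is None
        assert s.n_valid_frames == 0 and s.valid_duration_min == 0.0


class TestDetectFailure:
    def test_no_parseable_co(self):
        failed, reason = detect_failure([], n_ecs_lines=50, n_ecs_rejected=50)
        assert failed and reason is FailureReason.NO_CO_SIGNAL

    def test_fully_valid_session(self):
        frames = [valid_frame(0.0, 5.0, 11.0, 0.98)]
        failed, reason = detect_failure(frames, n_ecs_lines=1, n_ecs_rejected=0)
        assert not failed and reason is FailureReason.OK

    def test_below_threshold_fraction(self):
        # 5% of CO lines parseable, under the 10% detectability floor
        frames = [valid_frame(0.0, 5.0, 11.0, 0.98)]
        failed, reason = detect_failure(frames, n_ecs_lines=100, n_ecs_rejected=95)
        assert failed and reason is FailureReason.NO_CO_SIGNAL

    def test_co_present_but_no_valid_frames(self):
        frames = [invalid_frame(0.0)]
        failed, reason = detect_failure(frames, n_ecs_lines=10, n_ecs_rejected=0)
        assert failed and reason is FailureReason.NO_VALID_FRAMES
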
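import numpy as np
import pytest

from blinkscope.blinkmatrix import MATRIX_WIDTH, BlinkMatrix
from blinkscope.phases import (
    DisplacementTrace,
    NotABlinkError,
    PhaseSegmentation,
    analyze_trace,
    blink_parameters,
    classify_blink,
    displacement_trace,
    parameters_from_durations,
    segment_phases,
)


def _trace(d, fps=240.0):
    return DisplacementTrace(d=np.asarray(d, dtype=float), fps=fps)


def _cosine_blink(depth, open_frames=30, close_frames=25, hold_frames=0,
                  reopen_frames=45, fps=240.0):
    """Smooth synthetic trace: open -> descend -> hold -> ascend -> open."""
    u = np.linspace(0, 1, close_frames, endpoint=False)
    down = 0.7 - depth * np.sin(np.pi * u / 2) ** 2
    v = np.linspace(0, 1, reopen_frames, endpoint=False)
    up = 0.7 - depth * np.cos(np.pi * v / 2) ** 2
    d = np.concatenate([
        np.full(open_frames, 0.7), down, np.full(hold_frames, 0.7 - depth),
        up, np.full(open_frames, 0.7),
    ])
    return _trace(d, fps)


class TestDisplacementTrace:
    def test_constant_matrix_gives_constant_trace(self):
        bm = BlinkMatrix(m=np.full((7, MATRIX_WIDTH), 0.7), fps=240.0, norm_params=(0.0, 1.0))
        trace = displacement_trace(bm)
        np.testing.assert_allclose(trace.d, 0.7)

    def test_tracks_ground_truth_on_fixture(self, fixtures, analyzed):
        seq, gt = fixtures["NORMAL"]
        blink = analyzed["NORMAL"].blinks[0]
        start = round(blink.clip.frames.t0 * seq.fps)
        truth = gt.displacement[start:start + len(blink.record.trace)]
        assert np.abs(blink.record.trace.d - truth).max() <= 0.05

    def test_incomplete_fixture_minimum(self, analyzed):
        trace = analyzed["INCOMPLETE"].blinks[0].record.trace
        assert trace.d.min() == pytest.approx(0.456, abs=0.05)


class TestSegmentPhases:
    def test_dip_below_complete_level_marks_closed(self):
        trace = _cosine_blink(depth=0.49, hold_frames=7)  # floor at 0.21
        seg = segment_phases(trace)
        assert seg.complete
        c_lo, c_hi = seg.closed
        assert (trace.d[c_lo:c_hi] < 0.25).all()
        assert c_hi - c_lo >= 7

    def test_shallow_blink_has_no_closed_phase(self):
        trace = _cosine_blink(depth=0.244)  # minimum 0.456
        seg = segment_phases(trace)
        assert not seg.complete
        assert seg.closed[0] == seg.closed[1]

    def test_gap_band_between_levels_is_not_complete(self):
        trace = _cosine_blink(depth=0.42)  # minimum 0.28, inside (0.25, 0.3)
        seg = segment_phases(trace)
        assert not seg.complete

    def test_phases_are_contiguous_and_cover_span(self):
        trace = _cosine_blink(depth=0.5, hold_frames=10)
        seg = segment_phases(trace)
        assert seg.closing[1] == seg.closed[0]
        assert seg.closed[1] == seg.opening[0]
        assert seg.span == (seg.closing[0], seg.opening[1])

    def test_monotone_trace_is_not_a_blink(self):
        with pytest.raises(NotABlinkError):
            segment_phases(_trace(np.linspace(0.7, 0.2, 50)))

    def test_flat_trace_is_not_a_blink(self):
        with pytest.raises(NotABlinkError):
            segment_phases(_trace(np.full(50, 0.7)))


class TestClassify:
    def test_consecutive_on_double_dip_without_reopen(self):
        t1 = _cosine_blink(depth=0.35, open_frames=20, reopen_frames=20)
        # second, deeper dip begins from a partial reopen at ~0.55
        u = np.linspace(0, 1, 25)
        descend = 0.55 - 0.35 * np.sin(np.pi * u / 2) ** 2
        v = np.linspace(0, 1, 40)
        rise = 0.2 + 0.5 * np.sin(np.pi * v / 2) ** 2
        d = np.concatenate([t1.d[:62], descend, rise, np.full(20, 0.7)])
        trace = _trace(d)
        seg = segment_phases(trace)
        assert classify_blink(trace, seg) == "consecutive"

    def test_two_separate_blinks_with_full_reopen_are_not_consecutive(self):
        one = _cosine_blink(depth=0.5, hold_frames=6, open_frames=25)
        d = np.concatenate([one.d, one.d])  # full return to 0.7 in between
        trace = _trace(d)
        seg = segment_phases(trace)
        assert classify_blink(trace, seg) != "consecutive"

    def test_incomplete_when_minimum_above_threshold(self):
        trace = _cosine_blink(depth=0.244)
        seg = segment_phases(trace)
        assert classify_blink(trace, seg) == "incomplete"

    def test_gap_band_stays_normal(self):
        """Minimum in (0.25, 0.3): no closed phase, but closure is essentially
        full, so the pattern is not labeled incomplete."""
        trace = _cosine_blink(depth=0.42)
        seg = segment_phases(trace)
        assert classify_blink(trace, seg) == "normal"

    def test_fixture_labels(self, analyzed):
        expected = {"NORMAL": "normal", "INCOMPLETE": "incomplete",
                    "PROLONGED": "normal", "CONSECUTIVE": "consecutive"}
        for name, want in expected.items():
            assert analyzed[name].blinks[0].record.label == want


class TestParameters:
    def test_durations_sum_exactly(self):
        trace = _cosine_blink(depth=0.5, hold_frames=12)
        record = analyze_trace(trace)
        p = record.params
        assert p["total_duration_ms"] == pytest.approx(
            p["closing_ms"] + p["closed_ms"] + p["opening_ms"]
        )

    def test_closed_ratio_from_printed_phases(self):
        # phase durations realized exactly at 1000 fps (1 frame = 1 ms)
        d = np.concatenate([
            np.linspace(0.7, 0.25, 116, endpoint=False),
            np.full(30, 0.2),
            np.linspace(0.25, 0.7, 216),
        ])
        seg = PhaseSegmentation(closing=(0, 116), closed=(116, 146),
                                opening=(146, 362), complete=True)
        p = blink_parameters(_trace(d, fps=1000.0), seg)
        assert p["total_duration_ms"] == pytest.approx(362)
        assert round(p["closed_ratio_pct"], 1) == 8.3

    def test_total_displacement_from_initial_and_minimum(self):
        d = np.concatenate([np.full(5, 0.7), np.linspace(0.7, 0.456, 20),
                            np.linspace(0.456, 0.7, 20)])
        seg = PhaseSegmentation(closing=(0, 24), closed=(24, 24),
                                opening=(24, 45), complete=False)
        p = blink_parameters(_trace(d), seg)
        assert p["total_displacement"] == pytest.approx(0.244, abs=1e-9)

    def test_closing_faster_than_opening_when_closing_shorter(self, analyzed):
        for name in ("NORMAL", "PROLONGED"):
            p = analyzed[name].blinks[0].record.params
            assert p["closing_speed"] > p["opening_speed"] > 0

    def test_zero_length_phase_speed_is_missing(self):
        trace = _cosine_blink(depth=0.244)
        record = analyze_trace(trace)
        assert record.params["closed_ms"] == 0.0
        assert record.params["closing_speed"] is not None


class TestParametersFromDurations:
    def test_normal_worked_example(self):
        p = parameters_from_durations(116, 30, 216)
        assert p["total_duration_ms"] == 362
        assert round(p["closed_ratio_pct"], 1) == 8.3

    def test_prolonged_worked_example(self):
        p = parameters_from_durations(125, 208, 192)
        assert p["total_duration_ms"] == 525
        assert round(p["closed_ratio_pct"]) == 40

    def test_displacement_excursion(self):
        p = parameters_from_durations(70, 0, 92.5, min_displacement=0.456)
        assert p["total_displacement"] == pytest.approx(0.244)
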
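"""Constant-dose segment extraction, drift regression, dose-matched comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bspquant import dose as D
from bspquant.records import MedicationRecord
from conftest import make_traj

H = 3600.0


def _meds(steps, boluses=(), sid="S01"):
    return MedicationRecord(
        {"propofol": list(steps)},
        {"propofol": list(boluses)} if boluses else {},
        subject_id=sid,
    )


def _traj(duration_h, p=0.8, epoch_len=60.0):
    n = int(duration_h * H / epoch_len)
    return make_traj(np.full(n, p), epoch_len=epoch_len)


class TestSegmentExtraction:
    def test_ten_hour_window_trimmed_to_nine(self):
        meds = _meds([(0.0, 2.0), (10 * H, 3.0)])
        segs = D.extract_constant_segments(meds, _traj(12))
        assert len(segs) >= 1
        seg = segs[0]
        assert seg.start == 1800.0 and seg.end == 10 * H - 1800.0
        assert seg.duration_h == pytest.approx(9.0)
        assert seg.dose_combo == {"propofol": 2.0}

    def test_exactly_two_hours_keeps_one_hour(self):
        meds = _meds([(0.0, 2.0), (2 * H, 3.0), (10 * H, 4.0)])
        segs = D.extract_constant_segments(meds, _traj(12))
        first = segs[0]
        assert first.duration_h == pytest.approx(1.0)

    def test_window_below_two_hours_dropped(self):
        meds = _meds([(0.0, 2.0), (1.9 * H, 3.0), (12 * H, 4.0)])
        segs = D.extract_constant_segments(meds, _traj(12))
        assert all(s.start >= 1.9 * H for s in segs)

    def test_bolus_discards_whole_window(self):
        meds = _meds([(0.0, 2.0), (2.5 * H, 3.0), (12 * H, 4.0)], boluses=[(1.0 * H, 1.0)])
        segs = D.extract_constant_segments(meds, _traj(12))
        assert all(s.start >= 2.5 * H for s in segs)

    def test_low_median_bsp_dropped(self):
        meds = _meds([(0.0, 2.0)])
        segs = D.extract_constant_segments(meds, _traj(6, p=0.02))
        assert segs == []

    def test_repeated_identical_rate_is_not_a_change(self):
        meds = _meds([(0.0, 2.0), (5 * H, 2.0)])
        segs = D.extract_constant_segments(meds, _traj(10))
        assert len(segs) == 1 and segs[0].duration_h == pytest.approx(9.0)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(st.floats(0, 11), st.floats(0, 5)), max_size=6))
    def test_segments_respect_guard_everywhere(self, raw_steps):
        steps = sorted({(round(t * H), round(r, 1)) for t, r in raw_steps})
        meds = _meds([(0.0, 2.0)] + [(float(t), r) for t, r in steps if t > 0])
        segs = D.extract_constant_segments(meds, _traj(12))
        for s in segs:
            for t in meds.change_times():
                assert not (s.start - 1800.0 < t < s.end + 1800.0)


class TestDriftFit:
    def _seg(self, times, bsp):
        return D.ConstantDoseSegment(0, 1, {}, np.asarray(times), np.asarray(bsp))

    def test_exact_line(self):
        t = np.arange(0, 8 * H, 60.0)
        slope, intercept, _ = D.fit_drift(self._seg(t, 0.3 + 2.4 * t / 86400.0))
        assert slope == pytest.approx(2.4)
        assert intercept == pytest.approx(0.3)

    def test_flat_is_constant(self):
        t = np.arange(0, 4 * H, 60.0)
        slope, _, trend = D.fit_drift(self._seg(t, np.full(len(t), 0.8)))
        assert slope == pytest.approx(0.0) and trend == "constant"

    def test_noisy_slope_recovered(self, rng):
        t = np.arange(0, 8 * H, 1.0)
        y = 0.4 + 3.0 * t / 86400.0 + rng.normal(0, 0.05, len(t))
        slope, _, trend = D.fit_drift(self._seg(t, y))
        assert abs(slope - 3.0) < 0.3 and trend == "increasing"

    def test_noisy_flat_is_varying(self, rng):
        t = np.arange(0, 8 * H, 60.0)
        y = 0.5 + 0.25 * np.sin(2 * np.pi * t / (4 * H))
        slope, _, trend = D.fit_drift(self._seg(t, y))
        assert trend == "varying"

    def test_degenerate_time_axis_rejected(self):
        with pytest.raises(ValueError):
            D.fit_drift(self._seg([5.0, 5.0], [0.5, 0.6]))


class TestSlopeToDelta:
    @pytest.mark.parametrize(
        "slope,minutes,expected",
        [(6.77, 30.0, 6.77 * 30 / 1440), (0.0, 123.0, 0.0), (2.4, 60.0, 0.1)],
    )
    def test_arithmetic(self, slope, minutes, expected):
        assert D.slope_to_delta(slope, minutes) == pytest.approx(expected)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            D.slope_to_delta(1.0, 0.0)


def _segment(sid, combo, bsp):
    return D.ConstantDoseSegment(0, 1, combo, np.arange(len(bsp)), np.asarray(bsp),
                                 subject_id=sid)


class TestDoseMatching:
    def test_exact_match_after_rounding(self):
        segs = [
            _segment("A", {"propofol": 3.0}, np.full(10, 0.5)),
            _segment("B", {"propofol": 3.0}, np.full(10, 0.9)),
            _segment("C", {"propofol": 2.9}, np.full(10, 0.7)),
        ]
        groups = D.match_dose_groups(segs)
        assert len(groups) == 1
        assert set(groups[0].members) == {"A", "B"}

    def test_different_drug_sets_not_grouped(self):
        segs = [
            _segment("A", {"midazolam": 0.1, "propofol": 3.0}, np.full(10, 0.5)),
            _segment("B", {"propofol": 3.0}, np.full(10, 0.9)),
        ]
        assert D.match_dose_groups(segs) == []

    def test_three_subjects_three_pairwise_comparisons(self):
        segs = [_segment(s, {"propofol": 2.0}, np.full(10, p))
                for s, p in [("A", 0.3), ("B", 0.5), ("C", 0.7)]]
        groups = D.match_dose_groups(segs)
        assert len(groups) == 1 and len(groups[0].comparisons) == 3

    def test_comparisons_oriented_lower_median_first(self):
        segs = [
            _segment("HI", {"propofol": 2.0}, np.full(10, 0.9)),
            _segment("LO", {"propofol": 2.0}, np.full(10, 0.2)),
        ]
        (lo, hi, p), = D.match_dose_groups(segs)[0].comparisons
        assert (lo, hi) == ("LO", "HI") and p == 1.0


class TestExceedance:
    def test_identical_multisets_half(self):
        x = np.array([1.0, 2.0, 2.0, 5.0])
        assert D.exceedance_probability(x, x) == pytest.approx(0.5)

    def test_fully_separated_is_one(self):
        assert D.exceedance_probability([1, 2, 3], [4, 5]) == 1.0

    def test_interleaved_example(self):
        assert D.exceedance_probability([1, 3], [2, 4]) == pytest.approx(0.75)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            D.exceedance_probability([], [1.0])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=12),
        st.lists(st.integers(0, 5), min_size=1, max_size=12),
    )
    def test_brute_force_oracle_and_tie_convention(self, x, y):
        brute = sum(
            1.0 if a < b else 0.5 if a == b else 0.0 for a in x for b in y
        ) / (len(x) * len(y))
        p = D.exceedance_probability(x, y)
        assert p == pytest.approx(brute)
        assert p + D.exceedance_probability(y, x) == pytest.approx(1.0)

    def test_subsampled_path_close_to_exact(self, rng):
        x = rng.normal(0, 1, 5000)
        y = rng.normal(0.3, 1, 5000)
        exact = D.exceedance_probability(x, y)
        approx = D.exceedance_probability(x, y, max_pairs=10**6, seed=7)
        assert abs(exact - approx) < 0.01
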
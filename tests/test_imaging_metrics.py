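"""The C - C0 trial metric, responsiveness and direction-selectivity
indices, and the fittable-unit filter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_schedule
from omrkit.imaging_metrics import (
    compute_trial_response,
    dsi_series,
    extract_roi_traces,
    filter_fittable,
    max_c_minus_c0,
    pair_left_right,
    responsiveness_index,
    segment_trials,
    trial_responses,
)
from omrkit.synthetic_imaging import ImagingProtocol, UnitTrace, build_block_schedule


def trace_from_trials(trial_frames, stimuli, unit_id="u"):
    """UnitTrace whose frames are given explicitly per trial."""
    sched = make_schedule(stimuli)
    f = np.concatenate([np.asarray(t, dtype=float) for t in trial_frames])
    return UnitTrace(unit_id, np.arange(len(f), dtype=float), f, sched), sched


def step_trial(motion_value, baseline=0.0, post=None):
    """60-frame trial: 10 baseline, 30 motion, 20 post frames."""
    post = baseline if post is None else post
    return np.concatenate(
        [np.full(10, baseline), np.full(30, motion_value), np.full(20, post)]
    )


class TestSegmentTrials:
    def test_one_hour_block_is_60_by_60(self):
        sched = build_block_schedule("acute", 1, seed=0)
        n = len(sched.trials) * 60
        tr = UnitTrace("u", np.arange(n, dtype=float), np.zeros(n), sched)
        mat = segment_trials(tr)
        assert mat.shape == (180, 60)

    def test_short_trace_rejected(self):
        sched = build_block_schedule("acute", 1, seed=0)
        tr = UnitTrace("u", np.arange(100.0), np.zeros(100), sched)
        with pytest.raises(ValueError, match="shorter"):
            segment_trials(tr)

    def test_concatenated_blocks_preserve_trial_numbering(self):
        sched = build_block_schedule("acute", 2, seed=0)
        assert [t.index for t in sched.trials] == list(range(240))


class TestComputeTrialResponse:
    def test_constant_trace_is_identically_zero(self):
        r = compute_trial_response(np.full(60, 7.0))
        assert np.all(r.c_minus_c0 == 0.0) and r.trial_mean == 0.0

    def test_step_response_arithmetic(self):
        r = compute_trial_response(step_trial(150.0, baseline=100.0))
        assert r.c0 == 100.0
        assert np.all(r.c_minus_c0[10:40] == 50.0)
        assert np.all(r.c_minus_c0[:10] == 0.0)

    def test_zero_baseline_is_finite(self):
        """The subtraction metric stays finite where a ratio to baseline
        would be undefined."""
        r = compute_trial_response(step_trial(80.0, baseline=0.0))
        assert r.c0 == 0.0
        assert np.isfinite(r.trial_mean) and r.trial_mean > 0

    def test_motion_window_option(self):
        frames = step_trial(60.0, baseline=0.0)
        full = compute_trial_response(frames, window="full")
        motion = compute_trial_response(frames, window="motion")
        assert motion.trial_mean == pytest.approx(60.0)
        assert full.trial_mean == pytest.approx(30.0)  # 30 of 60 frames

    @given(
        st.lists(
            st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
            min_size=60,
            max_size=60,
        )
    )
    def test_baseline_window_mean_is_exactly_zero(self, frames):
        r = compute_trial_response(np.array(frames))
        assert abs(r.c_minus_c0[:10].mean()) < 1e-9


class TestResponsivenessIndex:
    def test_max_abs_normalization_oracle(self):
        ri = responsiveness_index([2.0, 4.0, -1.0])
        np.testing.assert_allclose(ri.values, [0.5, 1.0, -0.25])
        assert ri.sign_of_net_response == 1

    def test_net_increasing_unit_peaks_at_plus_one(self):
        ri = responsiveness_index([1.0, 3.0, 2.0])
        assert ri.values.max() == 1.0

    def test_net_decreasing_unit_peaks_at_minus_one(self):
        ri = responsiveness_index([-1.0, -5.0, 0.0])
        assert ri.values.min() == -1.0
        assert ri.sign_of_net_response == -1

    def test_all_zero_unit_is_flagged_unresponsive(self):
        ri = responsiveness_index([0.0, 0.0])
        assert ri.unresponsive and np.all(ri.values == 0.0)

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_values_bounded_with_attained_extreme(self, means):
        ri = responsiveness_index(means)
        assert np.all(np.abs(ri.values) <= 1.0)
        if any(m != 0 for m in means):
            assert np.abs(ri.values).max() == 1.0


class TestDSISeries:
    def test_left_only_responder_is_plus_one(self):
        """Constant positive response on left trials, zero on right trials:
        every pair difference normalizes to exactly +1."""
        means = [5.0, 0.0, 5.0, 0.0]
        ds = dsi_series(means, ["left", "right", "left", "right"])
        assert np.all(ds.values == 1.0)

    def test_right_only_responder_is_minus_one(self):
        means = [0.0, 5.0, 0.0, 5.0]
        ds = dsi_series(means, ["left", "right", "left", "right"])
        assert np.all(ds.values == -1.0)

    def test_max_abs_pair_normalization_oracle(self):
        ds = dsi_series([2.0, 0.0, 0.0, 4.0], ["left", "right", "left", "right"])
        np.testing.assert_allclose(ds.values, [0.5, -1.0])

    def test_equal_responses_give_zero(self):
        ds = dsi_series([3.0, 3.0], ["left", "right"])
        assert np.all(ds.values == 0.0)

    def test_no_pairs_flagged_empty(self):
        ds = dsi_series([1.0, 2.0], ["right", "left"][::-1])
        ds2 = dsi_series([1.0, 2.0], ["right", "right"])
        assert ds2.empty and len(ds2.values) == 0

    def test_pairing_skips_nonconforming_adjacencies(self):
        assert pair_left_right(["right", "left", "right"]) == [(1, 2)]
        assert pair_left_right(["left", "right", "left", "right"]) == [
            (0, 1), (2, 3),
        ]
        assert pair_left_right(["left", "left", "right"]) == [(1, 2)]
        assert pair_left_right(["left", "right", "right"]) == [(0, 1)]

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=4,
            max_size=40,
        ).map(lambda v: v[: len(v) // 2 * 2])
    )
    def test_values_bounded(self, means):
        stimuli = ["left", "right"] * (len(means) // 2)
        ds = dsi_series(means, stimuli)
        assert np.all(np.abs(ds.values) <= 1.0)


class TestFittableFilter:
    def _trace_with_peak(self, peak, unit_id="u"):
        trial = np.concatenate([np.zeros(10), np.full(30, peak), np.zeros(20)])
        return trace_from_trials([trial, np.zeros(60)], ["left", "right"], unit_id)[0]

    def test_threshold_boundary(self):
        kept = self._trace_with_peak(150.0, "kept")
        excluded = self._trace_with_peak(50.0, "excluded")
        exact = self._trace_with_peak(100.0, "exact")
        out = filter_fittable([kept, excluded, exact])
        assert [t.unit_id for t in out] == ["kept"]
        assert max_c_minus_c0(exact) == 100.0

    def test_max_spans_whole_experiment(self):
        """A unit quiet early but strong late still passes the filter."""
        quiet = np.zeros(60)
        loud = np.concatenate([np.zeros(10), np.full(30, 200.0), np.zeros(20)])
        tr, _ = trace_from_trials([quiet, loud], ["left", "left"])
        assert filter_fittable([tr]) == [tr]


class TestExtractRoiTraces:
    def test_uniform_frames_give_constant_trace(self):
        movie = np.full((5, 8, 8), 3.0)
        import pandas as pd

        rois = pd.DataFrame([{"unit_id": "u", "x0": 2, "y0": 2, "x1": 6, "y1": 6}])
        out = extract_roi_traces(movie, rois)[0]
        np.testing.assert_allclose(out.f, 3.0)

    def test_single_pixel_roi(self):
        movie = np.zeros((4, 5, 5))
        movie[:, 2, 3] = np.arange(4.0)
        import pandas as pd

        rois = pd.DataFrame([{"unit_id": "u", "x0": 3, "y0": 2, "x1": 4, "y1": 3}])
        out = extract_roi_traces(movie, rois)[0]
        np.testing.assert_allclose(out.f, np.arange(4.0))

    def test_out_of_bounds_roi_rejected(self):
        import pandas as pd

        movie = np.zeros((2, 4, 4))
        rois = pd.DataFrame([{"unit_id": "u", "x0": 0, "y0": 0, "x1": 5, "y1": 2}])
        with pytest.raises(ValueError, match="bounds"):
            extract_roi_traces(movie, rois)
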
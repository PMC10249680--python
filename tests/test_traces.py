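"""Trace preprocessing: masking, gap interpolation, epoch extraction."""

import numpy as np
import pytest

from vrsft import (
    PupilTrace,
    build_protocol,
    epoch_amplitude,
    interpolate_gaps,
    mask_invalid,
    schedule_events,
    segment_epochs,
    session_usable,
    simulate_session,
    NoiseParams,
    SubjectParams,
)


def flat_trace(n=200, fs=100.0, diameter=4.0):
    """A constant-diameter binocular trace for rule-level tests."""
    t = np.arange(n) / fs
    d = np.full(n, diameter)
    z = np.zeros(n)
    return PupilTrace(
        time_s=t,
        right_intensity_frac=z.copy(), left_intensity_frac=z.copy(),
        right_pupil_mm=d.copy(), left_pupil_mm=d.copy(),
        right_gaze_x=z.copy(), right_gaze_y=z.copy(),
        left_gaze_x=z.copy(), left_gaze_y=z.copy(),
        valid_right=np.ones(n, bool), valid_left=np.ones(n, bool),
    )


class TestMaskInvalid:
    def test_clean_trace_untouched(self):
        masked = mask_invalid(flat_trace())
        assert masked.valid_right.all() and masked.valid_left.all()

    def test_sentinel_flags_exactly_that_sample(self):
        tr = flat_trace()
        tr.right_pupil_mm[50] = -1.0
        masked = mask_invalid(tr)
        assert not masked.valid_right[50]
        assert masked.valid_right.sum() == len(tr) - 1
        assert masked.valid_left.all()  # per-eye rule
        # values are flagged, never modified
        assert masked.right_pupil_mm[50] == -1.0

    def test_out_of_range_diameters_flagged(self):
        tr = flat_trace()
        tr.left_pupil_mm[10] = 0.8  # below 1 mm
        tr.left_pupil_mm[20] = 10.5
        masked = mask_invalid(tr)
        assert not masked.valid_left[10] and not masked.valid_left[20]

    def test_jump_rule_invalidates_post_step_sample(self):
        tr = flat_trace()
        tr.right_pupil_mm[100:] = 5.0  # 1.0 mm step at sample 100
        masked = mask_invalid(tr, jump_limit_mm=0.5)
        assert not masked.valid_right[100]
        assert masked.valid_right[99] and masked.valid_right[101]

    def test_idempotent(self):
        tr = flat_trace()
        tr.right_pupil_mm[30] = -1.0
        tr.right_pupil_mm[60:] += 1.0
        once = mask_invalid(tr)
        twice = mask_invalid(once)
        np.testing.assert_array_equal(once.valid_right, twice.valid_right)
        np.testing.assert_array_equal(once.valid_left, twice.valid_left)


class TestInterpolateGaps:
    def test_identity_on_valid_trace(self):
        tr = flat_trace()
        out = interpolate_gaps(tr)
        np.testing.assert_array_equal(out.right_pupil_mm, tr.right_pupil_mm)
        assert not out.imputed_right.any()

    def test_single_sample_linear_midpoint(self):
        tr = flat_trace(fs=100.0)
        tr.right_pupil_mm[49] = 4.0
        tr.right_pupil_mm[51] = 4.2
        tr.right_pupil_mm[50] = -1.0
        tr.valid_right[50] = False
        out = interpolate_gaps(tr)
        assert out.right_pupil_mm[50] == pytest.approx(4.1)
        assert out.valid_right[50]
        assert out.imputed_right[50]

    def test_long_gap_untouched(self):
        tr = flat_trace(n=500, fs=100.0)
        tr.valid_right[100:301] = False  # 2 s gap
        out = interpolate_gaps(tr, max_gap_s=0.5)
        assert not out.valid_right[100:301].any()
        assert not out.imputed_right.any()

    def test_idempotent_after_interpolation(self):
        tr = flat_trace(n=500, fs=100.0)
        tr.valid_right[100:110] = False  # short, repairable
        tr.valid_right[200:350] = False  # long, kept invalid
        once = interpolate_gaps(tr)
        twice = interpolate_gaps(once)
        np.testing.assert_array_equal(once.right_pupil_mm, twice.right_pupil_mm)
        np.testing.assert_array_equal(once.valid_right, twice.valid_right)


class TestSegmentEpochs:
    def test_one_epoch_per_illuminated_event(self, protocol1_schedule, noiseless_trace):
        epochs = segment_epochs(noiseless_trace, protocol1_schedule)
        assert len(epochs) == 30

    def test_epoch_count_robust_to_data_quality(self, protocol1_schedule, noiseless_trace):
        tr = noiseless_trace.copy()
        tr.valid_right[:] = False
        tr.valid_left[:] = False
        epochs = segment_epochs(tr, protocol1_schedule)
        assert len(epochs) == 30
        assert all(e.rejected for e in epochs)

    def test_constant_trace_zero_amplitudes(self, protocol1_schedule):
        tr = flat_trace(n=95 * 100, fs=100.0)
        epochs = segment_epochs(tr, protocol1_schedule)
        assert all(e.amplitude_mm == 0.0 for e in epochs if not e.rejected)

    def test_first_repetition_excluded_by_default(self, protocol1_schedule, noiseless_trace):
        epochs = segment_epochs(noiseless_trace, protocol1_schedule)
        assert sum(e.excluded for e in epochs) == 10  # 5 levels x 2 events
        assert all(e.excluded == (e.repetition_index == 1) for e in epochs)
        kept = segment_epochs(noiseless_trace, protocol1_schedule,
                              drop_first_repetition=False)
        assert not any(e.excluded for e in kept)

    def test_additive_shift_invariance(self, protocol1_schedule, noiseless_trace):
        shifted = noiseless_trace.copy()
        shifted.right_pupil_mm = shifted.right_pupil_mm + 0.7
        shifted.left_pupil_mm = shifted.left_pupil_mm + 0.7
        a = segment_epochs(noiseless_trace, protocol1_schedule)
        b = segment_epochs(shifted, protocol1_schedule)
        for ea, eb in zip(a, b):
            if not (ea.rejected or eb.rejected):
                assert eb.amplitude_mm == pytest.approx(ea.amplitude_mm, abs=1e-9)

    def test_short_trace_rejected(self, protocol1_schedule):
        tr = flat_trace(n=100, fs=100.0)  # 1 s, far short of 95 s
        with pytest.raises(ValueError):
            segment_epochs(tr, protocol1_schedule)

    def test_intensity_monotonicity_of_constriction(self, noiseless):
        """Stronger stimulation drives the pupil to a smaller diameter."""
        sched = schedule_events(build_protocol(1))
        tr = simulate_session(sched, SubjectParams(), noiseless, 0)
        epochs = [e for e in segment_epochs(tr, sched) if e.accepted]
        # right-eye stimulus fraction is 1.0 at level 1, 0.5 at level 2,
        # 0.25 at level 4: the constricted minimum must deepen with intensity
        min_by_level = {}
        for e in epochs:
            if e.stimulated_eye == "right":
                min_by_level.setdefault(e.level_index, []).append(e.min_mm)
        assert np.mean(min_by_level[1]) < np.mean(min_by_level[2])
        assert np.mean(min_by_level[2]) < np.mean(min_by_level[4])
        # and the rebound left-eye (100%) constriction amplitude grows with
        # how far the preceding attenuated stimulus let the pupil redilate
        amp_left = {}
        for e in epochs:
            if e.stimulated_eye == "left":
                amp_left.setdefault(e.level_index, []).append(e.amplitude_mm)
        assert np.mean(amp_left[4]) > np.mean(amp_left[2]) > np.mean(amp_left[1])


class TestEpochAmplitude:
    def test_subtraction_and_floor(self, protocol1_schedule, noiseless_trace):
        epochs = segment_epochs(noiseless_trace, protocol1_schedule)
        ep = next(e for e in epochs if not e.rejected)
        assert epoch_amplitude(ep) == pytest.approx(
            max(ep.baseline_mm - ep.min_mm, 0.0))

    def test_rejected_epoch_raises(self, protocol1_schedule, noiseless_trace):
        tr = noiseless_trace.copy()
        tr.valid_right[:] = False
        tr.valid_left[:] = False
        ep = segment_epochs(tr, protocol1_schedule)[0]
        with pytest.raises(ValueError):
            epoch_amplitude(ep)


class TestSessionUsable:
    def test_clean_session_usable(self, protocol1_schedule, noiseless_trace):
        epochs = segment_epochs(noiseless_trace, protocol1_schedule)
        assert session_usable(epochs)

    def test_heavy_blinker_unusable(self, protocol1_schedule, noiseless_trace):
        tr = noiseless_trace.copy()
        tr.valid_right[: len(tr) // 2] = False
        tr.valid_left[: len(tr) // 2] = False
        epochs = segment_epochs(tr, protocol1_schedule)
        assert not session_usable(epochs)
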
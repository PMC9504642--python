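"""Reference durations, piecewise-linear alignment and pooling."""

import numpy as np
import pandas as pd
import pytest

from vtatlas.core import ImageFrame, ImageSeries, SegmentAnnotation
from vtatlas.temporal import (
    GlobalSeries,
    ReferenceDurations,
    TimedSample,
    compute_reference_durations,
    piecewise_align,
    pool_global_series,
    trim_to_annotation,
)


def _series(n_frames, cv="tu", speaker="SP1", fps=50.0):
    frames = [ImageFrame(np.full((4, 4), float(k + 1)), frame_index=k) for k in range(n_frames)]
    return ImageSeries(frames=frames, fps=fps, speaker_id=speaker, cv_label=cv)


def _ref(cv="tu", c=8.0, v=5.0):
    return ReferenceDurations(c_frames={cv: c}, v_frames={cv: v})


class TestReferenceDurations:
    def test_single_annotation_mean(self):
        ann = SegmentAnnotation(c_onset=0, v_onset=7, v_offset=12)
        ref = compute_reference_durations([("tu", ann)], cv_labels=("tu",))
        assert ref.c_frames["tu"] == 7 and ref.v_frames["tu"] == 5

    def test_mean_of_two_annotations(self):
        anns = [
            ("tu", SegmentAnnotation(0, 6, 10)),
            ("tu", SegmentAnnotation(0, 8, 14)),
        ]
        ref = compute_reference_durations(anns, cv_labels=("tu",))
        assert ref.c_frames["tu"] == 7.0 and ref.v_frames["tu"] == 5.0

    def test_dataframe_input_and_total(self):
        df = pd.DataFrame(
            {"cv": ["pa", "pa"], "c_onset": [0, 2], "v_onset": [7, 10], "v_offset": [15, 19]}
        )
        ref = compute_reference_durations(df, cv_labels=("pa",))
        assert ref.cv_frames("pa") == pytest.approx(16.0)

    def test_missing_cv_listed_in_error(self):
        with pytest.raises(ValueError, match="pa"):
            compute_reference_durations(
                [("tu", SegmentAnnotation(0, 7, 12))], cv_labels=("tu", "pa")
            )

    def test_fractional_frames_convert_to_ms(self):
        ref = ReferenceDurations(c_frames={"tu": 7.025}, v_frames={"tu": 4.85})
        assert ref.c_seconds("tu", 50.0) * 1000 == pytest.approx(140.5)
        assert ref.cv_seconds("tu", 50.0) * 1000 == pytest.approx(237.5)


class TestPiecewiseAlign:
    def test_matching_durations_keep_original_frame_times(self):
        series = _series(13)
        ann = SegmentAnnotation(c_onset=0, v_onset=8, v_offset=13)
        samples = piecewise_align(series, ann, _ref(c=8.0, v=5.0))
        times = np.array([s.time for s in samples])
        np.testing.assert_allclose(times, np.arange(13) / 50.0, atol=1e-12)

    def test_double_stretch_of_consonant(self):
        # C of 4 frames onto a reference of 8 frames at 50 fps: 40 ms steps
        series = _series(9)
        ann = SegmentAnnotation(c_onset=0, v_onset=4, v_offset=9)
        samples = piecewise_align(series, ann, _ref(c=8.0, v=5.0))
        c_times = [s.time for s in samples[:4]]
        np.testing.assert_allclose(c_times, [0.0, 0.040, 0.080, 0.120], atol=1e-12)

    def test_compression_halves_spacing(self):
        # C of 8 frames onto a reference of 4 frames: 10 ms spacing
        series = _series(13)
        ann = SegmentAnnotation(c_onset=0, v_onset=8, v_offset=13)
        samples = piecewise_align(series, ann, _ref(c=4.0, v=5.0))
        c_times = np.array([s.time for s in samples[:8]])
        np.testing.assert_allclose(np.diff(c_times), 0.010, atol=1e-12)

    def test_vowel_starts_at_reference_consonant_end(self):
        series = _series(12)
        ann = SegmentAnnotation(c_onset=2, v_onset=6, v_offset=12)
        ref = _ref(c=7.0, v=5.0)
        samples = piecewise_align(series, ann, ref)
        v0 = samples[4]  # first vowel frame
        assert v0.time == pytest.approx(7.0 / 50.0)
        assert v0.source_frame_index == 6

    def test_alignment_preserves_count_order_and_total_duration(self):
        series = _series(20)
        ann = SegmentAnnotation(c_onset=3, v_onset=10, v_offset=18)
        ref = _ref(c=8.5, v=6.25)
        samples = piecewise_align(series, ann, ref)
        assert len(samples) == ann.v_offset - ann.c_onset
        times = [s.time for s in samples]
        assert times == sorted(times)
        # last frame lies within one frame period of the reference duration
        assert ref.cv_seconds("tu", 50.0) - times[-1] <= 1 / 50.0 + 1e-12

    def test_zero_length_segment_rejected(self):
        series = _series(5)
        with pytest.raises(ValueError):
            SegmentAnnotation(c_onset=2, v_onset=2, v_offset=5)


class TestTrim:
    def test_trim_drops_silence_and_trailing_p(self):
        series = _series(19)
        ann = SegmentAnnotation(c_onset=3, v_onset=10, v_offset=17)
        trimmed, shifted = trim_to_annotation(series, ann)
        assert len(trimmed) == 14
        assert trimmed.frames[0].frame_index == 3
        assert (shifted.c_onset, shifted.v_onset, shifted.v_offset) == (0, 7, 14)


class TestPooling:
    def _sample(self, t, speaker, idx=0):
        return TimedSample(
            image=ImageFrame(np.ones((4, 4))), time=t, speaker_id=speaker,
            source_frame_index=idx,
        )

    def test_single_speaker_passthrough(self):
        s = [self._sample(0.0, "SP1", 0), self._sample(0.02, "SP1", 1)]
        gs = pool_global_series([s], "tu", "M")
        assert [x.time for x in gs.samples] == [0.0, 0.02]

    def test_interleaved_merge_is_stable(self):
        a = [self._sample(0.0, "SP1"), self._sample(0.03, "SP1")]
        b = [self._sample(0.0, "SP2"), self._sample(0.015, "SP2")]
        gs = pool_global_series([a, b], "tu", "M")
        keys = [(s.time, s.speaker_id) for s in gs.samples]
        assert keys == sorted(keys)
        assert len(gs) == 4

    def test_count_conserved_with_duplicates_at_a_time_point(self):
        lists = [
            [self._sample(0.01 * k, f"SP{i}", k) for k in range(12)] for i in range(8)
        ]
        gs = pool_global_series(lists, "tu", "M")
        assert len(gs) == 96


class TestNormalizeSeries:
    def test_scaled_series_recovers_inverse_scale(self, small_cohort):
        from vtatlas.reference import build_reference_space
        from vtatlas.registration import (
            AffineTransform2D,
            CompositeTransform,
            RegistrationSettings,
            apply_transform,
        )
        from vtatlas.temporal import normalize_series

        st = RegistrationSettings(ffd_spacing=8.0)
        ref = build_reference_space(
            {s: small_cohort.silence(s, "M") for s in ["SP1", "SP2"]}, settings=st
        )
        base = ref.reference_image
        c = np.array([31.5, 31.5])
        # a 3-frame series that is the reference scaled up by 1.2
        grow = AffineTransform2D.from_center(np.eye(2) / 1.2, np.zeros(2), c)
        scaled = apply_transform(CompositeTransform(grow), base)
        series = ImageSeries(
            frames=[
                ImageFrame(scaled.pixels, frame_index=k) for k in range(3)
            ],
            fps=50.0,
            speaker_id="SPX",
            cv_label="tu",
        )
        normalized, affines = normalize_series(series, ref, settings=st)
        assert normalized.shape == series.shape
        # the recovered backward map must undo the 1.2x magnification
        for aff in affines:
            scale = np.sqrt(abs(np.linalg.det(aff.matrix)))
            assert scale == pytest.approx(1.2, rel=0.02)
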
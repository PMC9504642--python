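"""Anatomical normalization of dynamic series and piecewise-linear
temporal alignment onto a global time axis.

Dynamic CV series are mapped to the reference space with one affine per
frame (affine only, so the articulator configuration is preserved while
the anatomy is normalized).  Segment annotations then place every frame
on a global time axis: the consonant and vowel segments of each
utterance are independently linearly stretched or compressed so their
durations equal the cohort-average reference durations.  Pooling the
aligned frames of all speakers yields one irregularly-sampled global
series per CV and plane, possibly with several frames at one time
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CV_LABELS, ImageFrame, ImageSeries, SegmentAnnotation, match_histogram
from .reference import ReferenceSpace
from .registration import (
    AffineTransform2D,
    CompositeTransform,
    RegistrationSettings,
    apply_transform,
    register_affine,
)

__all__ = [
    "ReferenceDurations",
    "TimedSample",
    "GlobalSeries",
    "normalize_series",
    "compute_reference_durations",
    "piecewise_align",
    "pool_global_series",
]


@dataclass(frozen=True)
class ReferenceDurations:
    """Cohort-average consonant and vowel durations per CV, in frames.

    Durations are kept fractional; ``seconds`` converts at the given
    frame rate.
    """

    c_frames: Mapping[str, float]
    v_frames: Mapping[str, float]

    def __post_init__(self):
        for cv in self.c_frames:
            if self.c_frames[cv] <= 0 or self.v_frames.get(cv, 0) <= 0:
                raise ValueError(f"non-positive reference duration for {cv!r}")

    def cv_frames(self, cv: str) -> float:
        return self.c_frames[cv] + self.v_frames[cv]

    def c_seconds(self, cv: str, fps: float) -> float:
        return self.c_frames[cv] / fps

    def v_seconds(self, cv: str, fps: float) -> float:
        return self.v_frames[cv] / fps

    def cv_seconds(self, cv: str, fps: float) -> float:
        return self.cv_frames(cv) / fps

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"cv": cv, "c": self.c_frames[cv], "v": self.v_frames[cv],
             "cv_total": self.cv_frames(cv)}
            for cv in self.c_frames
        ]
        return pd.DataFrame(rows).set_index("cv")


@dataclass(frozen=True)
class TimedSample:
    """One anatomically-neutral frame placed on the global time axis."""

    image: ImageFrame
    time: float  # seconds
    speaker_id: str
    source_frame_index: int

    def __post_init__(self):
        if self.time < -1e-12:
            raise ValueError("sample time must be >= 0")


@dataclass
class GlobalSeries:
    """Frames of all speakers for one CV/plane on the global time axis."""

    cv_label: str
    plane: str
    samples: list[TimedSample] = field(default_factory=list)

    def __post_init__(self):
        self.samples = sorted(
            self.samples, key=lambda s: (s.time, s.speaker_id, s.source_frame_index)
        )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.samples])


def normalize_series(
    series: ImageSeries,
    ref: ReferenceSpace,
    settings: RegistrationSettings | None = None,
    init: AffineTransform2D | None = None,
) -> tuple[ImageSeries, list[AffineTransform2D]]:
    """Map every frame of a dynamic series to the reference space.

    Each frame is histogram-matched to the reference histogram and then
    affinely registered to the reference image — one independent affine
    per frame, no non-rigid part, so local articulator shape survives.
    Consecutive frames warm-start from the previous frame's solution;
    ``init`` (e.g. the speaker's silence-to-reference affine) seeds the
    first frame.

    Returns the normalized series and the per-frame affines.
    """
    if series.plane != ref.plane:
        raise ValueError(
            f"series plane {series.plane!r} does not match reference {ref.plane!r}"
        )
    out_frames: list[ImageFrame] = []
    affines: list[AffineTransform2D] = []
    prev: AffineTransform2D | None = init
    for k, frame in enumerate(series.frames):
        matched = match_histogram(frame, ref.histogram)
        try:
            aff = register_affine(
                matched, ref.reference_image, settings=settings, init=prev
            )
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"affine normalization failed at frame {k}") from exc
        warped = apply_transform(CompositeTransform(aff, None), matched)
        out_frames.append(warped.with_pixels(warped.pixels))
        affines.append(aff)
        prev = aff
    normalized = ImageSeries(
        frames=out_frames,
        fps=series.fps,
        speaker_id=series.speaker_id,
        cv_label=series.cv_label,
    )
    return normalized, affines


def compute_reference_durations(
    annotations: Iterable[tuple[str, SegmentAnnotation]] | pd.DataFrame,
    cv_labels: Sequence[str] = CV_LABELS,
) -> ReferenceDurations:
    """Average C and V durations (frames) per CV over speakers and planes.

    ``annotations`` is either an iterable of ``(cv_label, annotation)``
    pairs or a DataFrame with columns ``cv, c_onset, v_onset, v_offset``.
    """
    if isinstance(annotations, pd.DataFrame):
        df = annotations.copy()
        df["c"] = df["v_onset"] - df["c_onset"]
        df["v"] = df["v_offset"] - df["v_onset"]
    else:
        rows = [
            {"cv": cv, "c": ann.c_frames, "v": ann.v_frames}
            for cv, ann in annotations
        ]
        df = pd.DataFrame(rows)
    missing = [cv for cv in cv_labels if df.empty or cv not in set(df["cv"])]
    if missing:
        raise ValueError(f"no annotations for CV(s): {', '.join(missing)}")
    means = df.groupby("cv")[["c", "v"]].mean()
    return ReferenceDurations(
        c_frames={cv: float(means.loc[cv, "c"]) for cv in cv_labels},
        v_frames={cv: float(means.loc[cv, "v"]) for cv in cv_labels},
    )


def piecewise_align(
    series: ImageSeries,
    ann: SegmentAnnotation,
    ref: ReferenceDurations,
    fps: float | None = None,
) -> list[TimedSample]:
    """Place a CV utterance's frames on the global time axis.

    The consonant segment (``n_C`` frames) is linearly mapped onto
    ``[0, r_C/fps)`` and the vowel segment onto
    ``[r_C/fps, (r_C+r_V)/fps)``, where ``r_C, r_V`` are the reference
    durations in frames: the frame at offset ``f`` inside a segment of
    ``n`` frames gets time ``segment_start + (f/n) * segment_ref_len``.
    Only C and V frames are kept (leading silence and the trailing /p/
    are dropped).  The map is start-anchored and monotone; no
    frame-to-frame correspondence with the reference is imposed.
    """
    if fps is None:
        fps = series.fps
    ann.validate_for(series)
    cv = series.cv_label
    if cv not in ref.c_frames:
        raise ValueError(f"no reference durations for CV {cv!r}")
    n_c, n_v = ann.c_frames, ann.v_frames
    if n_c <= 0 or n_v <= 0:
        raise ValueError("zero-length segment")
    r_c = ref.c_seconds(cv, fps)
    r_v = ref.v_seconds(cv, fps)
    samples: list[TimedSample] = []
    for f in range(ann.c_onset, ann.v_offset):
        frame = series.frames[f]
        if f < ann.v_onset:
            t = (f - ann.c_onset) / n_c * r_c
        else:
            t = r_c + (f - ann.v_onset) / n_v * r_v
        samples.append(
            TimedSample(
                image=frame,
                time=t,
                speaker_id=series.speaker_id,
                source_frame_index=frame.frame_index,
            )
        )
    return samples


def trim_to_annotation(
    series: ImageSeries, ann: SegmentAnnotation
) -> tuple[ImageSeries, SegmentAnnotation]:
    """Drop the leading silence and the trailing /p/ frames at ingest.

    Only the C and V parts of an utterance enter the atlas; trimming
    before normalization avoids registering frames that are discarded
    anyway.  Original ``frame_index`` values are preserved.
    """
    ann.validate_for(series)
    trimmed = ImageSeries(
        frames=series.frames[ann.c_onset : ann.v_offset],
        fps=series.fps,
        speaker_id=series.speaker_id,
        cv_label=series.cv_label,
    )
    shifted = SegmentAnnotation(
        c_onset=0, v_onset=ann.c_frames, v_offset=ann.c_frames + ann.v_frames
    )
    return trimmed, shifted


def normalize_and_align(
    series: ImageSeries,
    ann: SegmentAnnotation,
    ref: ReferenceSpace,
    durations: ReferenceDurations,
    settings: RegistrationSettings | None = None,
    init: AffineTransform2D | None = None,
) -> list[TimedSample]:
    """Trim to the annotated C+V window, normalize, and align in time."""
    trimmed, shifted = trim_to_annotation(series, ann)
    normalized, _ = normalize_series(trimmed, ref, settings=settings, init=init)
    return piecewise_align(normalized, shifted, durations, fps=series.fps)


def pool_global_series(
    aligned: Sequence[Sequence[TimedSample]], cv_label: str, plane: str
) -> GlobalSeries:
    """Pool per-speaker aligned samples into one time-sorted series.

    Samples at identical time points are preserved; ordering is stable
    by (time, speaker_id, source_frame_index).
    """
    samples = [s for speaker_samples in aligned for s in speaker_samples]
    return GlobalSeries(cv_label=cv_label, plane=plane, samples=samples)
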
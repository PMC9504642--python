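"""Anatomically-neutral reference ("silence") space construction.

One silence frame per speaker (quiet nasal breathing, closed mouth) is
taken per plane.  Every speaker's frame is non-rigidly registered to
every other speaker's frame; the N-1 transforms of each speaker are
averaged parameter-wise to give that speaker's average transform
``T̄_i``; applying ``T̄_i`` to speaker i's frame yields the neutralized
image ``Ī_i``; the pixel-wise mean of the ``Ī_i`` is the reference
image ``Ī``.  The process is repeated independently per plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageFrame, IntensityHistogram, average_histogram, compute_histogram, match_histogram
from .registration import (
    CompositeTransform,
    RegistrationSettings,
    average_transforms,
    apply_transform,
    register_bspline,
)

__all__ = ["ReferenceSpace", "build_reference_space"]


@dataclass
class ReferenceSpace:
    """Per-plane anatomically-neutral space.

    Attributes
    ----------
    reference_image
        The speaker-independent reference image ``Ī``.
    speaker_transforms
        ``T̄_i`` per speaker id: the average of speaker i's pairwise
        registrations to all other speakers.
    neutral_images
        ``Ī_i = T̄_i(I_i)`` per speaker id.
    histogram
        The cohort average histogram all inputs were matched to.
    """

    plane: str
    reference_image: ImageFrame
    speaker_transforms: dict[str, CompositeTransform]
    neutral_images: dict[str, ImageFrame]
    histogram: IntensityHistogram

    @property
    def n_speakers(self) -> int:
        return len(self.speaker_transforms)


def build_reference_space(
    silence_images: dict[str, ImageFrame],
    plane: str | None = None,
    settings: RegistrationSettings | None = None,
) -> ReferenceSpace:
    """Build the reference space from one silence frame per speaker.

    Steps: (a) compute the average intensity histogram and match every
    input to it; (b) run all N(N-1) pairwise B-spline registrations
    T_{i,j} (moving = speaker i, fixed = speaker j); (c) average each
    speaker's N-1 transforms; (d) warp each speaker by its average
    transform; (e) pixel-wise mean of the warped images.
    """
    if len(silence_images) < 2:
        raise ValueError("reference space needs at least 2 speakers")
    speakers = sorted(silence_images)
    frames = [silence_images[s] for s in speakers]
    shape = frames[0].shape
    if plane is None:
        plane = frames[0].plane
    for s, f in zip(speakers, frames):
        if f.shape != shape or f.plane != plane:
            raise ValueError(f"speaker {s}: all silence frames must share shape and plane")

    # (a) intensity normalization to the cohort average histogram
    lo = min(float(f.pixels.min()) for f in frames)
    hi = max(float(f.pixels.max()) for f in frames)
    if hi == lo:
        hi = lo + 1.0
    hists = [compute_histogram(f, value_range=(lo, hi)) for f in frames]
    avg_hist = average_histogram(hists)
    matched = {s: match_histogram(f, avg_hist) for s, f in zip(speakers, frames)}

    # (b) all pairwise registrations, (c) per-speaker averages
    speaker_transforms: dict[str, CompositeTransform] = {}
    neutral: dict[str, ImageFrame] = {}
    for i in speakers:
        pair_transforms = []
        for j in speakers:
            if j == i:
                continue
            try:
                t = register_bspline(matched[i], matched[j], settings=settings)
            except Exception as exc:  # pragma: no cover - diagnostics path
                raise RuntimeError(f"registration failed for pair ({i}, {j})") from exc
            pair_transforms.append(t)
        t_bar = average_transforms(pair_transforms)
        speaker_transforms[i] = t_bar
        neutral[i] = apply_transform(t_bar, matched[i])

    # (e) pixel-wise mean
    ref = np.mean([neutral[s].pixels for s in speakers], axis=0)
    reference_image = ImageFrame(ref, plane=plane, frame_index=0)
    return ReferenceSpace(
        plane=plane,
        reference_image=reference_image,
        speaker_transforms=speaker_transforms,
        neutral_images=neutral,
        histogram=avg_hist,
    )
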
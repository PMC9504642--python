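"""Core data model: image frames, series, segment annotations and
intensity histograms.

The vocal-tract imaging pipeline works on 2D grayscale sagittal frames
(nominally 136x136 pixels at 50 frames/s) acquired in five parallel
planes R2, R1, M, L1, L2 (right-of-center to left-of-center).  Before
every transformation or averaging step, images are histogram-matched so
that intensity differences between speakers and acquisitions do not
leak into the registration metric — the matching primitives live here.

Coordinate convention used throughout the package: 0-based,
``x`` = column index, ``y`` = row index, pixel-centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PLANES",
    "CV_LABELS",
    "ImageFrame",
    "ImageSeries",
    "SegmentAnnotation",
    "IntensityHistogram",
    "compute_histogram",
    "average_histogram",
    "match_histogram",
]

#: The five parallel sagittal acquisition planes, right to left.
PLANES = ("R2", "R1", "M", "L1", "L2")

#: The 12 consonant-vowel syllables under study.
CV_LABELS = tuple(c + v for c in "fpst" for v in "iau")

DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class ImageFrame:
    """A single 2D grayscale frame.

    Parameters
    ----------
    pixels
        ``(M, W)`` matrix of non-negative pixel density values
        (arbitrary units).
    plane
        One of :data:`PLANES`.
    frame_index
        0-based index of the frame inside its acquisition series.
    """

    pixels: np.ndarray
    plane: str = "M"
    frame_index: int = 0

    def __post_init__(self):
        pixels = np.asarray(self.pixels, dtype=float)
        if pixels.ndim != 2 or pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D matrix")
        if not np.all(np.isfinite(pixels)):
            raise ValueError("pixel intensities must be finite")
        if pixels.min() < 0:
            raise ValueError("pixel intensities must be non-negative")
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}; expected one of {PLANES}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        object.__setattr__(self, "pixels", pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ImageFrame":
        return replace(self, pixels=pixels)


@dataclass
class ImageSeries:
    """An ordered time series of frames from one speaker, plane and CV."""

    frames: list[ImageFrame]
    fps: float = 50.0
    speaker_id: str = ""
    cv_label: str = "silence"

    def __post_init__(self):
        if not self.frames:
            raise ValueError("series must contain at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        shape = self.frames[0].shape
        plane = self.frames[0].plane
        for f in self.frames:
            if f.shape != shape:
                raise ValueError("all frames in a series must share one shape")
            if f.plane != plane:
                raise ValueError("all frames in a series must share one plane")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")
        if self.cv_label != "silence" and self.cv_label not in CV_LABELS:
            raise ValueError(f"unknown cv_label {self.cv_label!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def plane(self) -> str:
        return self.frames[0].plane

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def stack(self) -> np.ndarray:
        """Pixels as a ``(T, M, W)`` array."""
        return np.stack([f.pixels for f in self.frames])


@dataclass(frozen=True)
class SegmentAnnotation:
    """Phoneme segment boundaries for one CV utterance.

    ``c_onset`` is the first frame of the consonant constriction (e.g.
    first tongue-tip/teeth contact for /t/), ``v_onset`` the first frame
    with the constriction released, and ``v_offset`` the first frame of
    the trailing /p/ lip contact.  All indices are 0-based frame indices
    into the annotated :class:`ImageSeries`.
    """

    c_onset: int
    v_onset: int
    v_offset: int

    def __post_init__(self):
        if not (0 <= self.c_onset < self.v_onset < self.v_offset):
            raise ValueError(
                "annotation must satisfy 0 <= c_onset < v_onset < v_offset"
            )

    @property
    def c_frames(self) -> int:
        """Consonant duration in frames."""
        return self.v_onset - self.c_onset

    @property
    def v_frames(self) -> int:
        """Vowel duration in frames."""
        return self.v_offset - self.v_onset

    def validate_for(self, series: ImageSeries) -> None:
        if self.v_offset > len(series):
            raise ValueError(
                f"annotation v_offset {self.v_offset} exceeds series length "
                f"{len(series)}"
            )


@dataclass(frozen=True)
class IntensityHistogram:
    """Binned intensity distribution with explicit bin edges."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or counts.ndim != 1 or len(counts) != len(edges) - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("histogram must have positive total mass")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def cdf(self) -> np.ndarray:
        """Cumulative distribution over bins, normalized to end at 1."""
        c = np.cumsum(self.counts)
        return c / c[-1]


def compute_histogram(
    image: ImageFrame,
    n_bins: int = DEFAULT_N_BINS,
    value_range: tuple[float, float] | None = None,
) -> IntensityHistogram:
    """Histogram of an image's intensities.

    ``value_range`` defaults to the image's own [min, max] (widened to a
    unit interval for constant images so the binning stays valid).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pix = image.pixels
    if value_range is None:
        lo, hi = float(pix.min()), float(pix.max())
        if lo == hi:
            hi = lo + 1.0
        value_range = (lo, hi)
    counts, edges = np.histogram(pix, bins=n_bins, range=value_range)
    return IntensityHistogram(bin_edges=edges, counts=counts.astype(float))


def average_histogram(histograms: Sequence[IntensityHistogram]) -> IntensityHistogram:
    """Arithmetic mean of normalized histograms, rescaled to a common mass.

    Each input is first normalized to a probability histogram (images may
    have different pixel counts after cropping), the probabilities are
    averaged bin-wise, and the result is rescaled to the mean input mass.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    edges = histograms[0].bin_edges
    for h in histograms[1:]:
        if h.bin_edges.shape != edges.shape or not np.allclose(h.bin_edges, edges):
            raise ValueError("histograms must share identical bin_edges")
    probs = np.mean([h.counts / h.total for h in histograms], axis=0)
    mass = float(np.mean([h.total for h in histograms]))
    return IntensityHistogram(bin_edges=edges, counts=probs * mass)


def match_histogram(image: ImageFrame, reference: IntensityHistogram) -> ImageFrame:
    """Transform an image's intensities so its histogram matches a reference.

    Monotone CDF inversion: every distinct pixel value is assigned its
    empirical quantile, and mapped to the center of the lowest
    reference bin whose cumulative mass reaches that quantile (ties map
    to the lowest admissible intensity, deterministically).  A value
    already lying inside its target bin passes through untouched, which
    makes an image whose histogram already equals the reference a
    bit-exact fixed point, and the mapping idempotent (matching twice
    equals matching once).
    """
    edges = reference.bin_edges
    centers = reference.bin_centers
    n_bins = len(reference.counts)
    pix = image.pixels
    vals, inv, counts = np.unique(pix.ravel(), return_inverse=True, return_counts=True)
    quantiles = np.cumsum(counts) / pix.size
    ref_cdf = reference.cdf()
    # lowest target bin t with ref_cdf[t] >= quantile of the value
    target = np.searchsorted(ref_cdf, quantiles, side="left")
    target = np.clip(target, 0, n_bins - 1)
    lo, hi = edges[target], edges[target + 1]
    inside = (vals >= lo) & ((vals < hi) | ((target == n_bins - 1) & (vals <= hi)))
    out_vals = np.where(inside, vals, centers[target])
    matched = out_vals[inv].reshape(pix.shape)
    return image.with_pixels(np.maximum(matched, 0.0))
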
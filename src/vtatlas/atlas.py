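"""Atlas frame synthesis by adaptive Gaussian kernel regression.

An atlas frame at time ``τ`` is the Gaussian-weighted average of the
``k`` global-series samples nearest to ``τ`` in time.  "Adaptive" means
the kernel width is rescaled per synthesis point so that the same
number of samples contributes everywhere: with ``τ_f`` the farthest of
the k selected sample times, the variance is set to

    σ² = −(τ − τ_f)² / (2 ln 0.35)

so that the unnormalized weight at ``τ_f`` is exactly 0.35 of the peak
weight at ``τ``.  If all selected samples sit exactly at ``τ`` the
weights degenerate to uniform.  Because the synthesis times are free,
the atlas frame rate is independent of the acquisition frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import numpy as np

from .core import ImageFrame, compute_histogram, match_histogram
from .temporal import GlobalSeries

__all__ = [
    "KernelConfig",
    "AtlasFrame",
    "Atlas",
    "adaptive_kernel_weights",
    "synthesize_frame",
    "build_atlas",
    "default_time_grid",
]

#: Weight retained at the farthest selected sample, relative to the peak.
WEIGHT_FLOOR_RATIO = 0.35


@dataclass(frozen=True)
class KernelConfig:
    """Adaptive Gaussian kernel parameters.

    ``k`` samples per synthesized frame (default 7); ``window`` the
    nominal sampling window in seconds (default 20 ms, one acquisition
    frame period) used as the default synthesis-grid spacing and as a
    sanity bound; ``weight_floor_ratio`` the relative weight assigned
    to the farthest selected sample.
    """

    k: int = 7
    window: float = 0.020
    weight_floor_ratio: float = WEIGHT_FLOOR_RATIO

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not (0.0 < self.weight_floor_ratio < 1.0):
            raise ValueError("weight_floor_ratio must be in (0, 1)")


@dataclass(frozen=True)
class AtlasFrame:
    """One synthesized frame with its kernel provenance."""

    image: ImageFrame
    time: float
    contributors: tuple[tuple[str, int, float], ...]  # (speaker, source_frame, weight)


@dataclass
class Atlas:
    """Synthesized frames per CV and plane, sharing one time grid per CV."""

    frames: dict[str, dict[str, list[AtlasFrame]]]  # cv -> plane -> frames
    config: KernelConfig
    provenance: dict = field(default_factory=dict)

    def time_grid(self, cv: str) -> np.ndarray:
        planes = self.frames[cv]
        first = next(iter(planes.values()))
        return np.array([f.time for f in first])


def kernel_raw_weights(
    sample_times: Sequence[float], tau: float, cfg: KernelConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """k-nearest selection and UNNORMALIZED Gaussian weights (peak = 1).

    Selection tie-break at equal |t − τ|: earlier time, then lower
    index.  With ``σ² = −(τ−τ_f)²/(2 ln r)`` the raw weight
    ``exp(−d²/2σ²)`` equals ``r^((d/τ_f−τ)²)``, which is exact at the
    floor (``r`` at the farthest sample) and immune to underflow for
    tiny spans.  When every selected sample sits at ``τ`` the raw
    weights are all 1 (σ degenerates; uniform).
    """
    cfg = cfg or KernelConfig()
    times = np.asarray(sample_times, dtype=float)
    if times.size == 0:
        raise ValueError("empty sample series")
    delta = np.abs(times - tau)
    order = np.lexsort((np.arange(times.size), times, delta))
    sel = np.sort(order[: cfg.k])
    d = delta[sel]
    far = float(d.max())
    if far > cfg.window:
        warnings.warn(
            f"farthest selected sample is {far * 1000:.1f} ms from the synthesis "
            f"point, beyond the {cfg.window * 1000:.0f} ms window",
            stacklevel=2,
        )
    if far == 0.0:
        return sel, np.ones(sel.size)
    raw = cfg.weight_floor_ratio ** ((d / far) ** 2)
    return sel, raw


def adaptive_kernel_weights(
    sample_times: Sequence[float], tau: float, cfg: KernelConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Select the k nearest samples to ``tau`` and weight them.

    Returns ``(indices, weights)`` with the Gaussian weights of
    :func:`kernel_raw_weights` normalized to sum to 1 (so the synthesis
    is a weighted average).
    """
    sel, raw = kernel_raw_weights(sample_times, tau, cfg)
    return sel, raw / raw.sum()


def synthesize_frame(
    gs: GlobalSeries,
    tau: float,
    cfg: KernelConfig | None = None,
    match_contributors: bool = True,
) -> AtlasFrame:
    """Synthesize the atlas frame at time ``tau``.

    The k nearest samples are histogram-matched to the contributor
    nearest in time (so intensity scales agree before averaging) and
    combined as a pixel-wise weighted average with the adaptive kernel
    weights.  ``match_contributors=False`` skips the intensity matching
    and averages the raw contributor images.
    """
    cfg = cfg or KernelConfig()
    if len(gs) == 0:
        raise ValueError("empty global series")
    idx, weights = adaptive_kernel_weights(gs.times, tau, cfg)
    selected = [gs.samples[i] for i in idx]
    nearest = selected[int(np.argmin([abs(s.time - tau) for s in selected]))]
    ref_hist = compute_histogram(nearest.image)
    imgs = []
    for s in selected:
        if match_contributors and s is not nearest:
            img = match_histogram(s.image, ref_hist)
        else:
            img = s.image
        imgs.append(img.pixels)
    pixels = np.einsum("k,kij->ij", weights, np.stack(imgs))
    frame = ImageFrame(np.maximum(pixels, 0.0), plane=gs.plane, frame_index=0)
    contributors = tuple(
        (s.speaker_id, s.source_frame_index, float(w))
        for s, w in zip(selected, weights)
    )
    return AtlasFrame(image=frame, time=float(tau), contributors=contributors)


def default_time_grid(duration: float, spacing: float = 0.020) -> np.ndarray:
    """Regular synthesis grid 0, spacing, ... covering ``duration``."""
    n = int(np.floor(duration / spacing + 1e-9)) + 1
    return np.arange(n) * spacing


def build_atlas(
    series_by_plane: Mapping[str, Mapping[str, GlobalSeries]],
    time_grids: Mapping[str, Sequence[float]],
    cfg: KernelConfig | None = None,
    provenance: dict | None = None,
) -> Atlas:
    """Synthesize the full atlas: one frame per (CV, plane, grid time).

    ``series_by_plane`` maps cv -> plane -> GlobalSeries; all planes of
    a CV share the time grid ``time_grids[cv]``.
    """
    cfg = cfg or KernelConfig()
    frames: dict[str, dict[str, list[AtlasFrame]]] = {}
    for cv, planes in series_by_plane.items():
        grid = np.asarray(time_grids[cv], dtype=float)
        frames[cv] = {}
        for plane, gs in planes.items():
            frames[cv][plane] = [synthesize_frame(gs, t, cfg) for t in grid]
    return Atlas(frames=frames, config=cfg, provenance=provenance or {})
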
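"""Cross-validated atlas evaluation.

Four folds: six training speakers build the atlas, two held-out test
speakers (one per gender) are mapped to it.  Each test CV is
piecewise-linearly aligned to the atlas time axis; each atlas frame is
linked to the temporally closest test frame of each test speaker (test
frames may be reused or unused).  A frame stack then holds the atlas
image A, the two original (unregistered) test images O1, O2, and the
same images non-rigidly registered to A, R1, R2.  Similarity before
the atlas (BA) and after it (AA) is the maximum zero-padded 2D
cross-correlation of the pair of test images, normalized by the
maximum autocorrelation of A:

    BA = max_lags Σ O1[m,w] O2[m-k, w-l]  /  max_lags Σ A[m,w] A[m-f, w-g]

(and AA likewise with R1, R2), with lags ranging over all integers
−(M−1)..M−1 and −(W−1)..W−1.  Values are pooled over frames, planes
and folds into per-CV mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .atlas import Atlas, AtlasFrame, KernelConfig, build_atlas, default_time_grid
from .core import ImageFrame, compute_histogram, match_histogram
from .reference import build_reference_space
from .registration import RegistrationSettings, apply_transform, register_bspline
from .temporal import (
    TimedSample,
    compute_reference_durations,
    normalize_and_align,
    pool_global_series,
)

__all__ = [
    "FoldSpec",
    "FrameStack",
    "SimilarityReport",
    "make_folds",
    "link_frames",
    "xcorr_similarity",
    "run_validation",
]


@dataclass(frozen=True)
class FoldSpec:
    """One cross-validation fold: train/test speaker split."""

    fold_id: int
    train: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ValueError("train and test speakers must be disjoint")


@dataclass
class FrameStack:
    """Atlas frame A with linked test frames, before/after registration."""

    atlas: ImageFrame
    originals: tuple[ImageFrame, ImageFrame]  # O1, O2
    registered: tuple[ImageFrame, ImageFrame]  # R1, R2

    def __post_init__(self):
        shapes = {self.atlas.shape} | {f.shape for f in self.originals} | {
            f.shape for f in self.registered
        }
        if len(shapes) != 1:
            raise ValueError("all five stack images must share one shape")


@dataclass
class SimilarityReport:
    """Per-CV pooled similarity before (BA) and after (AA) the atlas."""

    table: pd.DataFrame  # index cv; columns mean_before, sd_before, mean_after, sd_after
    samples: pd.DataFrame  # one row per stack: cv, plane, fold, time, ba, aa

    @classmethod
    def from_samples(cls, samples: pd.DataFrame) -> "SimilarityReport":
        grouped = samples.groupby("cv")
        table = pd.DataFrame(
            {
                "mean_before": grouped["ba"].mean(),
                "sd_before": grouped["ba"].std(ddof=0),
                "mean_after": grouped["aa"].mean(),
                "sd_after": grouped["aa"].std(ddof=0),
            }
        )
        return cls(table=table, samples=samples)


def make_folds(
    genders: Mapping[str, str], n_folds: int = 4, seed: int = 0
) -> list[FoldSpec]:
    """Deterministic folds with one male + one female test speaker each.

    Requires ``n_folds`` speakers of each gender; every speaker is
    tested exactly once.
    """
    males = sorted(s for s, g in genders.items() if g.upper().startswith("M"))
    females = sorted(s for s, g in genders.items() if g.upper().startswith("F"))
    if len(males) != n_folds or len(females) != n_folds:
        raise ValueError(
            f"need {n_folds} male and {n_folds} female speakers, "
            f"got {len(males)}M/{len(females)}F"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(males)
    rng.shuffle(females)
    everyone = set(males) | set(females)
    folds = []
    for i in range(n_folds):
        test = (males[i], females[i])
        train = tuple(sorted(everyone - set(test)))
        folds.append(FoldSpec(fold_id=i, train=train, test=test))
    return folds


def link_frames(
    atlas_times: Sequence[float], test_samples: Sequence[TimedSample]
) -> list[int]:
    """For each atlas time, the index of the temporally closest test
    sample (ties broken toward the earlier test frame).  Test frames may
    be linked more than once; some may go unused."""
    if len(atlas_times) == 0 or len(test_samples) == 0:
        raise ValueError("need non-empty atlas times and test samples")
    t = np.array([s.time for s in test_samples])
    out = []
    for tau in atlas_times:
        d = np.abs(t - tau)
        out.append(int(np.argmin(d)))  # argmin takes the first (earlier) on ties
    return out


def _max_xcorr(x: np.ndarray, y: np.ndarray) -> float:
    """Max over all zero-padded integer lags of the 2D cross-correlation."""
    return float(signal.correlate(x, y, mode="full", method="auto").max())


def xcorr_similarity(a: ImageFrame, x: ImageFrame, y: ImageFrame) -> float:
    """Normalized peak cross-correlation similarity of a frame stack.

    ``max_lags xcorr(X, Y) / max_lags autocorr(A)`` with full zero
    padding over lags −(M−1)..M−1, −(W−1)..W−1.
    """
    if not (a.shape == x.shape == y.shape):
        raise ValueError("A, X, Y must share one shape")
    denom = _max_xcorr(a.pixels, a.pixels)
    if denom <= 0:
        raise ValueError("atlas frame has zero autocorrelation")
    return _max_xcorr(x.pixels, y.pixels) / denom


@dataclass
class ValidationConfig:
    """Scales and settings for the cross-validation driver."""

    kernel: KernelConfig = field(default_factory=KernelConfig)
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)
    planes: Sequence[str] = ("M",)
    cv_labels: Sequence[str] | None = None
    atlas_grid_spacing: float = 0.020
    fps: float = 50.0
    n_folds: int = 4
    seed: int = 0


def run_validation(dataset, config: ValidationConfig | None = None) -> SimilarityReport:
    """Four-fold cross-validation of atlas construction on a dataset.

    ``dataset`` provides (see :class:`vtatlas.phantom.PhantomDataset`):
    ``speakers`` (id -> gender), ``silence(speaker, plane)`` one
    ImageFrame, ``series(speaker, cv, plane)`` an ImageSeries and
    ``annotation(speaker, cv, plane)`` a SegmentAnnotation.

    Per fold: build the reference space and atlas from the training
    speakers; affinely normalize and piecewise-align the test CVs;
    link each atlas frame to the closest test frame per test speaker;
    histogram-match the linked frames to the atlas frame; register
    them to it with the B-spline method; and score BA/AA per stack.
    """
    cfg = config or ValidationConfig()
    from .core import CV_LABELS

    cv_labels = list(cfg.cv_labels or CV_LABELS)
    folds = make_folds(dict(dataset.speakers), n_folds=cfg.n_folds, seed=cfg.seed)
    rows = []
    for fold in folds:
        rows.extend(_run_fold(dataset, fold, cv_labels, cfg))
    samples = pd.DataFrame(rows)
    return SimilarityReport.from_samples(samples)


def _run_fold(dataset, fold: FoldSpec, cv_labels, cfg: ValidationConfig):
    reg = cfg.registration
    # reference durations from the training speakers (all planes)
    ann_pairs = [
        (cv, dataset.annotation(s, cv, p))
        for s in fold.train
        for cv in cv_labels
        for p in cfg.planes
    ]
    durations = compute_reference_durations(ann_pairs, cv_labels=cv_labels)

    rows = []
    for plane in cfg.planes:
        ref = build_reference_space(
            {s: dataset.silence(s, plane) for s in fold.train},
            plane=plane,
            settings=reg,
        )
        # one cold silence-to-reference affine per speaker seeds the
        # per-frame normalizations of all that speaker's CVs
        from .registration import register_affine

        speaker_init = {
            s: register_affine(dataset.silence(s, plane), ref.reference_image, settings=reg)
            for s in (*fold.train, *fold.test)
        }

        def aligned_samples(speaker: str, cv: str) -> list[TimedSample]:
            series = dataset.series(speaker, cv, plane)
            ann = dataset.annotation(speaker, cv, plane)
            return normalize_and_align(
                series, ann, ref, durations, settings=reg, init=speaker_init[speaker]
            )

        for cv in cv_labels:
            train_aligned = [aligned_samples(s, cv) for s in fold.train]
            gs = pool_global_series(train_aligned, cv_label=cv, plane=plane)
            grid = default_time_grid(
                durations.cv_seconds(cv, cfg.fps), cfg.atlas_grid_spacing
            )
            atlas = build_atlas({cv: {plane: gs}}, {cv: grid}, cfg.kernel)
            atlas_frames = atlas.frames[cv][plane]

            test_aligned = {s: aligned_samples(s, cv) for s in fold.test}
            links = {
                s: link_frames([f.time for f in atlas_frames], test_aligned[s])
                for s in fold.test
            }
            for fi, af in enumerate(atlas_frames):
                stack = _make_stack(
                    af,
                    [test_aligned[s][links[s][fi]] for s in fold.test],
                    reg,
                )
                ba = xcorr_similarity(stack.atlas, *stack.originals)
                aa = xcorr_similarity(stack.atlas, *stack.registered)
                rows.append(
                    {
                        "cv": cv,
                        "plane": plane,
                        "fold": fold.fold_id,
                        "time": af.time,
                        "ba": ba,
                        "aa": aa,
                    }
                )
    return rows


def _make_stack(
    atlas_frame: AtlasFrame, test_samples: Sequence[TimedSample],
    reg: RegistrationSettings,
) -> FrameStack:
    from .registration import AffineTransform2D

    a = atlas_frame.image
    a_hist = compute_histogram(a)
    originals = []
    registered = []
    for s in test_samples:
        o = match_histogram(s.image, a_hist)
        # test frames are already affinely normalized into the atlas space,
        # so the non-rigid stage starts from the identity
        t = register_bspline(o, a, settings=reg, affine=AffineTransform2D.identity())
        r = apply_transform(t, o)
        originals.append(o)
        registered.append(r)
    return FrameStack(
        atlas=a,
        originals=(originals[0], originals[1]),
        registered=(registered[0], registered[1]),
    )
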
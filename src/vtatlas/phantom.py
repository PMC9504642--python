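"""Synthetic multi-speaker vocal-tract phantom cohorts.

Real-time MRI recordings of speech are rarely shareable, so this module
renders a simplified but articulated 2D sagittal head — palate, tongue,
lips, jaw, pharyngeal wall and a variable-length spine — animated
through consonant-vowel gestures, for a cohort of speakers with known
anatomical differences.  Everything needed to exercise and verify the
atlas pipeline is exported as ground truth: the inter-speaker affine
maps, the per-utterance segment durations, and landmark sets for the
vocal-tract measurements.

Design notes:

* Anatomy differences are dominated by a per-speaker affine (global
  scale, head tilt, translation) applied analytically at render time,
  so the true transform between any two speakers' frames is known
  exactly.  Smaller non-affine differences (palate shape, tongue
  thickness, vertebra count, articulation amplitude) are superposed so
  that affine-only normalization leaves realistic residual variability
  for the non-rigid stages to explain.
* All speakers share one articulatory gesture per CV, sampled at
  speaker-specific consonant/vowel durations jittered around the
  configured cohort means; the piecewise-linear temporal alignment is
  therefore exercised non-trivially.
* Off-center sagittal planes are rendered with increasing blur and
  damped articulation, mimicking the partial-volume effect of thick
  slices away from the midline.
* Rendering uses smooth analytic indicator functions (logistic edges),
  so images are anti-aliased and have the gradients registration needs;
  no attempt is made at MRI realism beyond tissue/air contrast,
  Gaussian noise and blur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CV_LABELS, PLANES, ImageFrame, ImageSeries, SegmentAnnotation
from .measure import LandmarkSet
from .registration import AffineTransform2D

__all__ = [
    "PhantomSpeaker",
    "PhantomGesture",
    "PhantomDataset",
    "generate_cohort",
    "DEFAULT_DURATIONS",
]

#: Cohort-mean consonant and vowel durations per CV, in frames at 50 fps.
#: These are the study conditions the phantom emulates.
DEFAULT_DURATIONS: dict[str, tuple[float, float]] = {
    "fi": (9.0, 5.65),
    "fa": (8.175, 6.475),
    "fu": (7.525, 6.9),
    "pi": (6.55, 7.275),
    "pa": (7.475, 8.55),
    "pu": (6.6, 7.625),
    "si": (8.775, 5.875),
    "sa": (8.9, 6.05),
    "su": (9.025, 5.2),
    "ti": (7.6, 6.825),
    "ta": (6.85, 6.7),
    "tu": (7.025, 4.85),
}

N_LEAD_SILENCE = 3  # frames of initial silence posture per utterance
N_TRAIL_P = 2  # frames of the trailing /p/ closure

_PLANE_BLUR = {"M": 0.4, "R1": 1.0, "L1": 1.0, "R2": 1.8, "L2": 1.8}
_PLANE_DAMP = {"M": 1.0, "R1": 0.85, "L1": 0.85, "R2": 0.65, "L2": 0.65}


@dataclass(frozen=True)
class PhantomSpeaker:
    """Anatomical and intensity parameters of one synthetic speaker."""

    speaker_id: str
    gender: str  # "M" or "F"
    scale: float
    tilt_deg: float
    shift: tuple[float, float]  # pixels
    palate_offset: float  # canonical units, ~ +- 0.01
    jaw_offset: float
    tongue_thickness: float  # multiplicative, ~1
    n_vertebrae: int
    articulation_gain: float  # multiplicative, ~1
    intensity_gain: float
    intensity_offset: float

    def __post_init__(self):
        if not (0.85 <= self.scale <= 1.15):
            raise ValueError("speaker scale must lie in [0.85, 1.15]")

    def affine(self, image_size: int) -> AffineTransform2D:
        """Map from canonical image coordinates to this speaker's frame."""
        th = np.deg2rad(self.tilt_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        m = self.scale * rot
        c = np.array([(image_size - 1) / 2.0] * 2)
        return AffineTransform2D.from_center(m, np.asarray(self.shift), c)


@dataclass(frozen=True)
class PhantomGesture:
    """Speaker's realization of one CV: shared trajectory, own durations."""

    cv_label: str
    c_frames: int
    v_frames: int

    def __post_init__(self):
        if self.c_frames < 3 or self.v_frames < 3:
            raise ValueError("segment durations must be >= 3 frames")


# --------------------------------------------------------------------------
# articulatory targets and trajectories

_SILENCE = {"body": 0.40, "tip": 0.0, "back": 0.0, "aperture": 0.0, "jaw": 0.0}

_C_TARGETS = {
    "t": {"body": 0.30, "tip": 1.0, "back": -0.1, "aperture": 0.45, "jaw": 0.1},
    "s": {"body": 0.35, "tip": 0.85, "back": -0.1, "aperture": 0.35, "jaw": 0.1},
    "p": {"body": 0.40, "tip": 0.0, "back": 0.0, "aperture": 0.0, "jaw": 0.0},
    "f": {"body": 0.40, "tip": 0.0, "back": 0.0, "aperture": 0.12, "jaw": 0.05},
}

_V_TARGETS = {
    "i": {"body": 0.85, "tip": 0.15, "back": -0.35, "aperture": 0.45, "jaw": 0.15},
    "a": {"body": 0.10, "tip": 0.0, "back": 0.15, "aperture": 0.95, "jaw": 0.55},
    "u": {"body": 0.80, "tip": 0.0, "back": 0.50, "aperture": 0.25, "jaw": 0.10},
}

_P_CLOSURE = {"body": 0.40, "tip": 0.0, "back": 0.0, "aperture": 0.0, "jaw": 0.0}


def _ease(x: float) -> float:
    x = min(max(x, 0.0), 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * x)


def _blend(a: dict, b: dict, w: float) -> dict:
    return {k: (1 - w) * a[k] + w * b[k] for k in a}


def articulator_state(cv: str, phase: float) -> dict:
    """Articulator state along the shared gesture for one CV.

    ``phase`` runs from −1 (initial silence) through [0, 1) for the
    consonant, [1, 2) for the vowel, and beyond 2 for the trailing /p/
    closure.  The consonant target is fully reached at phase 0 (the
    consonant onset is defined by the first frame of contact) and the
    vowel target by mid-vowel.
    """
    c_t, v_t = _C_TARGETS[cv[0]], _V_TARGETS[cv[1]]
    if phase < 0.0:
        return _blend(_SILENCE, c_t, _ease(phase + 1.0))
    if phase < 1.0:
        # hold the constriction with a slight anticipatory drift
        return _blend(c_t, v_t, 0.15 * _ease(max(0.0, (phase - 0.6) / 0.4)))
    if phase < 2.0:
        w = _ease(min(1.0, (phase - 1.0) / 0.6))
        return _blend(_blend(c_t, v_t, 0.15), v_t, w)
    return _blend(v_t, _P_CLOSURE, _ease(min(1.0, (phase - 2.0))))


# --------------------------------------------------------------------------
# rendering


def _soft(d: np.ndarray, eps: float) -> np.ndarray:
    """Smooth 0→1 step of a signed quantity, edge width ~eps."""
    return 1.0 / (1.0 + np.exp(-np.clip(d / eps, -40, 40)))


def _render_canonical(u: np.ndarray, v: np.ndarray, spk: PhantomSpeaker,
                      art: dict, damp: float) -> np.ndarray:
    """Evaluate the scene at canonical coordinates (u right, v down) in
    [0, 1]; returns tissue intensity in [0, 1]."""
    eps = 0.008  # edge softness in canonical units
    g = spk.articulation_gain * damp
    body = art["body"] * g
    tip = art["tip"] * g
    back = art["back"] * g
    aperture = art["aperture"] * g
    jaw = art["jaw"] * g

    img = np.zeros_like(u)

    # posterior pharyngeal wall and neck tissue
    wall_u = 0.76 + 0.01 * np.sin(6.0 * v)
    img = np.maximum(img, 0.75 * _soft(u - wall_u, eps))

    # spine: alternating bright vertebra blocks behind the wall
    spine = np.zeros_like(u)
    for n in range(spk.n_vertebrae):
        vc = 0.22 + 0.13 * n
        spine = np.maximum(
            spine,
            np.exp(-(((u - 0.88) / 0.045) ** 2 + ((v - vc) / 0.045) ** 2)),
        )
    img = np.maximum(img, 0.95 * spine)

    # skull base / hard palate: tissue above the palate line
    palate_line = (
        0.34
        + spk.palate_offset
        - 0.10 * np.exp(-(((u - 0.38) / 0.22) ** 2))
    )
    img = np.maximum(img, 0.85 * _soft(palate_line - v, eps) * _soft(0.80 - u, eps))

    # tongue: tissue between its surface curve and the jaw floor
    tongue_surf = (
        0.66
        + jaw * 0.06
        - 0.26 * body * np.exp(-(((u - (0.44 + 0.14 * back)) / 0.17) ** 2))
        - 0.30 * tip * np.exp(-(((u - 0.20) / 0.055) ** 2))
    )
    tongue = (
        _soft(v - tongue_surf, eps)
        * _soft((0.90 + 0.05 * jaw) - v, eps)
        * _soft(u - 0.12, eps)
        * _soft(0.78 - u, eps)
    )
    img = np.maximum(img, (0.80 * spk.tongue_thickness) * tongue)

    # jaw / chin block under the mouth
    jaw_line = 0.88 + spk.jaw_offset + 0.07 * jaw
    img = np.maximum(
        img, 0.70 * _soft(v - jaw_line, eps) * _soft(0.55 - u, eps)
    )

    # lips: upper and lower blobs at the anterior end; the gap is the
    # lip aperture
    lip_mid = 0.52 + 0.05 * jaw
    half_gap = 0.015 + 0.11 * aperture
    for sign in (-1.0, 1.0):
        vc = lip_mid + sign * (half_gap + 0.035)
        img = np.maximum(
            img,
            0.90 * np.exp(-(((u - 0.085) / 0.035) ** 2 + ((v - vc) / 0.035) ** 2)),
        )

    # faint soft-tissue floor everywhere inside the head outline
    head = _soft(0.97 - v, 0.02) * _soft(v - 0.03, 0.02) * _soft(0.97 - u, 0.02)
    img = np.maximum(img, 0.12 * head * _soft(u - 0.02, 0.02))
    return img


def _render_frame(
    spk: PhantomSpeaker, art: dict, image_size: int, plane: str, rng, noise_sd: float
) -> np.ndarray:
    xx, yy = np.meshgrid(
        np.arange(image_size, dtype=float), np.arange(image_size, dtype=float)
    )
    inv = spk.affine(image_size).inverse()
    pts = np.stack([xx, yy], axis=-1)
    mapped = pts @ inv.matrix.T + inv.translation
    u = mapped[..., 0] / (image_size - 1)
    v = mapped[..., 1] / (image_size - 1)
    img = _render_canonical(u, v, spk, art, _PLANE_DAMP[plane])
    img = ndimage.gaussian_filter(img, _PLANE_BLUR[plane])
    img = spk.intensity_gain * img + spk.intensity_offset
    img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, None)


# --------------------------------------------------------------------------
# dataset container


@dataclass
class PhantomDataset:
    """A generated cohort with ground truth."""

    speakers: dict[str, str]  # speaker id -> gender
    fps: float
    image_size: int
    planes: tuple[str, ...]
    cv_labels: tuple[str, ...]
    speaker_params: dict[str, PhantomSpeaker]
    _silence: dict[tuple[str, str], ImageFrame] = field(default_factory=dict)
    _series: dict[tuple[str, str, str], ImageSeries] = field(default_factory=dict)
    _annotations: dict[tuple[str, str, str], SegmentAnnotation] = field(
        default_factory=dict
    )
    landmarks: dict[str, LandmarkSet] = field(default_factory=dict)
    durations: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def silence(self, speaker: str, plane: str) -> ImageFrame:
        return self._silence[(speaker, plane)]

    def series(self, speaker: str, cv: str, plane: str) -> ImageSeries:
        return self._series[(speaker, cv, plane)]

    def annotation(self, speaker: str, cv: str, plane: str) -> SegmentAnnotation:
        return self._annotations[(speaker, cv, plane)]

    def true_speaker_affine(self, speaker: str) -> AffineTransform2D:
        """Canonical-to-speaker affine (ground truth)."""
        return self.speaker_params[speaker].affine(self.image_size)

    def true_pair_affine(self, moving: str, fixed: str) -> AffineTransform2D:
        """Ground-truth transform T with I_moving(T(x)) ≈ I_fixed(x)."""
        a_m = self.true_speaker_affine(moving)
        a_f = self.true_speaker_affine(fixed)
        return a_m.compose(a_f.inverse())

    def iter_series(self):
        yield from self._series.items()


# canonical landmark geometry (canonical units), converted to mm with the
# nominal 1.41 mm in-plane resolution of a 136-px field of view
_MM_PER_CANONICAL = 1.41 * 136.0


def _speaker_landmarks(spk: PhantomSpeaker, image_size: int) -> LandmarkSet:
    aff = spk.affine(image_size)
    mm = _MM_PER_CANONICAL / (image_size - 1)

    def map_pt(uv):
        p = aff.apply_points(np.array([uv]) * (image_size - 1))[0]
        return (float(p[0] * mm), float(p[1] * mm))

    wall = tuple(map_pt((0.76 + 0.01 * np.sin(6.0 * v), v)) for v in np.linspace(0.1, 0.95, 18))
    return LandmarkSet(
        lip_contact_point=map_pt((0.085, 0.52)),
        axis_vertebra_point=map_pt((0.88, 0.48)),
        palate_tangent_point=map_pt((0.38, 0.24 + spk.palate_offset)),
        vocal_fold_point=map_pt((0.70, 0.93)),
        esophagus_point=map_pt((0.74, 0.95)),
        pharyngeal_wall=wall,
    )


def _gesture_phases(n_c: int, n_v: int) -> list[float]:
    phases = [(k - N_LEAD_SILENCE) / N_LEAD_SILENCE for k in range(N_LEAD_SILENCE)]
    phases += [k / n_c for k in range(n_c)]
    phases += [1.0 + k / n_v for k in range(n_v)]
    phases += [2.0 + (k + 1) / N_TRAIL_P for k in range(N_TRAIL_P)]
    return phases


def generate_cohort(
    n_speakers: int = 8,
    cv_list: tuple[str, ...] = CV_LABELS,
    fps: float = 50.0,
    planes: tuple[str, ...] = PLANES,
    image_size: int = 136,
    seed: int = 0,
    noise_sd: float = 0.01,
    duration_means: dict[str, tuple[float, float]] | None = None,
) -> PhantomDataset:
    """Generate a deterministic phantom cohort.

    One silence frame and one dynamic series per (speaker, CV, plane),
    with segment annotations and full ground truth.  ``seed`` fixes all
    randomness (anatomy, durations, noise) through a single generator.
    """
    if n_speakers < 2:
        raise ValueError("need at least 2 speakers")
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    for p in planes:
        if p not in PLANES:
            raise ValueError(f"unknown plane {p!r}")
    duration_means = duration_means or DEFAULT_DURATIONS
    rng = np.random.default_rng(seed)

    speakers: dict[str, str] = {}
    params: dict[str, PhantomSpeaker] = {}
    max_shift = 0.02 * image_size
    for i in range(n_speakers):
        sid = f"SP{i + 1}"
        gender = "M" if i % 2 == 0 else "F"
        # female speakers skew smaller, male larger, within [0.85, 1.15]
        base = 1.04 if gender == "M" else 0.96
        scale = float(np.clip(base + rng.uniform(-0.07, 0.07), 0.85, 1.15))
        params[sid] = PhantomSpeaker(
            speaker_id=sid,
            gender=gender,
            scale=scale,
            tilt_deg=float(rng.uniform(-4.0, 4.0)),
            shift=(
                float(rng.uniform(-max_shift, max_shift)),
                float(rng.uniform(-max_shift, max_shift)),
            ),
            palate_offset=float(rng.uniform(-0.012, 0.012)),
            jaw_offset=float(rng.uniform(-0.012, 0.012)),
            tongue_thickness=float(rng.uniform(0.94, 1.06)),
            n_vertebrae=int(rng.integers(4, 7)),
            articulation_gain=float(rng.uniform(0.92, 1.08)),
            intensity_gain=float(rng.uniform(0.92, 1.08)),
            intensity_offset=float(rng.uniform(0.0, 0.02)),
        )
        speakers[sid] = gender

    ds = PhantomDataset(
        speakers=speakers,
        fps=fps,
        image_size=image_size,
        planes=tuple(planes),
        cv_labels=tuple(cv_list),
        speaker_params=params,
    )
    for sid in speakers:
        ds.landmarks[sid] = _speaker_landmarks(params[sid], image_size)

    # speaker-specific integer durations jittered around the cohort means
    for sid in speakers:
        for cv in cv_list:
            mc, mv = duration_means[cv]
            n_c = max(3, int(round(mc)) + int(rng.integers(-1, 2)))
            n_v = max(3, int(round(mv)) + int(rng.integers(-1, 2)))
            ds.durations[(sid, cv)] = (n_c, n_v)

    for sid in speakers:
        spk = params[sid]
        for plane in planes:
            sil = _render_frame(
                spk, dict(_SILENCE), image_size, plane, rng, noise_sd
            )
            ds._silence[(sid, plane)] = ImageFrame(sil, plane=plane, frame_index=0)
        for cv in cv_list:
            n_c, n_v = ds.durations[(sid, cv)]
            phases = _gesture_phases(n_c, n_v)
            states = [articulator_state(cv, ph) for ph in phases]
            for plane in planes:
                frames = [
                    ImageFrame(
                        _render_frame(spk, st, image_size, plane, rng, noise_sd),
                        plane=plane,
                        frame_index=k,
                    )
                    for k, st in enumerate(states)
                ]
                ds._series[(sid, cv, plane)] = ImageSeries(
                    frames=frames, fps=fps, speaker_id=sid, cv_label=cv
                )
                ds._annotations[(sid, cv, plane)] = SegmentAnnotation(
                    c_onset=N_LEAD_SILENCE,
                    v_onset=N_LEAD_SILENCE + n_c,
                    v_offset=N_LEAD_SILENCE + n_c + n_v,
                )
    return ds
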
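"""Readers and writers for the package's on-disk formats.

Image series travel as NIfTI (time as the 3rd dimension) or multi-page
TIFF, each with a JSON sidecar carrying ``{speaker_id, plane, cv_label,
fps}``.  Segment annotations are CSV with columns ``speaker, plane, cv,
c_onset, v_onset, v_offset``.  Composite transforms and landmark sets
round-trip through JSON so pipelines can cache pairwise registrations.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import ImageFrame, ImageSeries, IntensityHistogram, SegmentAnnotation
from .measure import LandmarkSet
from .registration import AffineTransform2D, BSplineFFD, CompositeTransform

__all__ = [
    "save_series",
    "load_series",
    "save_annotations",
    "load_annotations",
    "transform_to_dict",
    "transform_from_dict",
    "save_transform",
    "load_transform",
    "save_landmarks",
    "load_landmarks",
    "histogram_to_dict",
    "histogram_from_dict",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_series(series: ImageSeries, path: str | Path) -> None:
    """Write a series as NIfTI (.nii/.nii.gz) or TIFF plus JSON sidecar."""
    path = Path(path)
    stack = series.stack()  # (T, M, W)
    if path.name.endswith((".nii", ".nii.gz")):
        # NIfTI stores (M, W, T)
        nib.save(nib.Nifti1Image(np.moveaxis(stack, 0, -1), np.eye(4)), str(path))
    elif path.name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), stack.astype(np.float32))
    else:
        raise ValueError(f"unsupported series format: {path.name}")
    meta = {
        "speaker_id": series.speaker_id,
        "plane": series.plane,
        "cv_label": series.cv_label,
        "fps": series.fps,
        "frame_indices": [f.frame_index for f in series.frames],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_series(path: str | Path) -> ImageSeries:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    if path.name.endswith((".nii", ".nii.gz")):
        data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        stack = np.moveaxis(data, -1, 0)
    elif path.name.endswith((".tif", ".tiff")):
        stack = np.asarray(tifffile.imread(str(path)), dtype=float)
        if stack.ndim == 2:
            stack = stack[None]
    else:
        raise ValueError(f"unsupported series format: {path.name}")
    indices = meta.get("frame_indices") or list(range(stack.shape[0]))
    frames = [
        ImageFrame(stack[k], plane=meta["plane"], frame_index=indices[k])
        for k in range(stack.shape[0])
    ]
    return ImageSeries(
        frames=frames,
        fps=float(meta["fps"]),
        speaker_id=meta["speaker_id"],
        cv_label=meta["cv_label"],
    )


def save_annotations(
    annotations: dict[tuple[str, str, str], SegmentAnnotation], path: str | Path
) -> None:
    """Annotations keyed (speaker, cv, plane) to CSV."""
    rows = [
        {
            "speaker": s,
            "plane": p,
            "cv": cv,
            "c_onset": a.c_onset,
            "v_onset": a.v_onset,
            "v_offset": a.v_offset,
        }
        for (s, cv, p), a in sorted(annotations.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_annotations(path: str | Path) -> dict[tuple[str, str, str], SegmentAnnotation]:
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[(str(row.speaker), str(row.cv), str(row.plane))] = SegmentAnnotation(
            c_onset=int(row.c_onset),
            v_onset=int(row.v_onset),
            v_offset=int(row.v_offset),
        )
    return out


def transform_to_dict(t: CompositeTransform) -> dict:
    d = {
        "affine": t.global_.params.tolist(),
        "local": None,
    }
    if t.local is not None:
        d["local"] = {
            "grid_shape": list(t.local.grid_shape),
            "spacing": list(t.local.spacing),
            "control_points": t.local.control_points.tolist(),
        }
    return d


def transform_from_dict(d: dict) -> CompositeTransform:
    aff = AffineTransform2D.from_params(d["affine"])
    local = None
    if d.get("local") is not None:
        ld = d["local"]
        local = BSplineFFD(
            np.asarray(ld["control_points"], dtype=float),
            tuple(ld["spacing"]),
        )
    return CompositeTransform(aff, local)


def save_transform(t: CompositeTransform, path: str | Path) -> None:
    Path(path).write_text(json.dumps(transform_to_dict(t)))


def load_transform(path: str | Path) -> CompositeTransform:
    return transform_from_dict(json.loads(Path(path).read_text()))


def histogram_to_dict(h: IntensityHistogram) -> dict:
    return {"bin_edges": h.bin_edges.tolist(), "counts": h.counts.tolist()}


def histogram_from_dict(d: dict) -> IntensityHistogram:
    return IntensityHistogram(
        np.asarray(d["bin_edges"], dtype=float), np.asarray(d["counts"], dtype=float)
    )


def save_landmarks(landmarks: dict[str, LandmarkSet], path: str | Path) -> None:
    out = {}
    for sid, lm in landmarks.items():
        out[sid] = {
            "lip_contact_point": list(lm.lip_contact_point),
            "axis_vertebra_point": list(lm.axis_vertebra_point),
            "palate_tangent_point": list(lm.palate_tangent_point),
            "vocal_fold_point": list(lm.vocal_fold_point),
            "esophagus_point": list(lm.esophagus_point),
            "pharyngeal_wall": [list(p) for p in lm.pharyngeal_wall],
        }
    Path(path).write_text(json.dumps(out, indent=1))


def load_landmarks(path: str | Path) -> dict[str, LandmarkSet]:
    raw = json.loads(Path(path).read_text())
    out = {}
    for sid, d in raw.items():
        out[sid] = LandmarkSet(
            lip_contact_point=tuple(d["lip_contact_point"]),
            axis_vertebra_point=tuple(d["axis_vertebra_point"]),
            palate_tangent_point=tuple(d["palate_tangent_point"]),
            vocal_fold_point=tuple(d["vocal_fold_point"]),
            esophagus_point=tuple(d["esophagus_point"]),
            pharyngeal_wall=tuple(tuple(p) for p in d["pharyngeal_wall"]),
        )
    return out
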
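"""2D affine + cubic B-spline free-form-deformation (FFD) registration.

The composite transform model is ADDITIVE::

    T(x, y) = T_global(x, y) + T_local(x, y)

where ``T_global`` is an affine map of the point and ``T_local`` is a
displacement interpolated from a regular control-point grid with the
cubic B-spline tensor product

    T_local(x, y) = sum_{l=0..3} sum_{m=0..3} B_l(u) B_m(v) phi_{i+l, j+m}

    i = floor(x/dx) - 1,  u = x/dx - floor(x/dx)   (same for j, v in y)

Images are warped by backward mapping with bilinear interpolation and
zero fill outside the domain.  Registration is performed in-house:
a multi-resolution Powell search over affine parameters driven by a
32-bin mutual-information metric, followed (for non-rigid registration)
by L-BFGS-B over the control displacements with an analytic
sum-of-squared-differences gradient.  Everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, optimize, sparse

from .core import ImageFrame

__all__ = [
    "AffineTransform2D",
    "BSplineFFD",
    "CompositeTransform",
    "bspline_basis",
    "bspline_displacement",
    "apply_transform",
    "register_affine",
    "register_bspline",
    "average_transforms",
    "mutual_information",
    "mean_endpoint_error",
    "RegistrationSettings",
]


# ---------------------------------------------------------------------------
# cubic B-spline basis


def bspline_basis(u: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis functions evaluated at ``u`` in [0, 1).

    Returns an array of shape ``u.shape + (4,)`` with
    ``B0 = (1-u)^3/6``, ``B1 = (3u^3-6u^2+4)/6``,
    ``B2 = (-3u^3+3u^2+3u+1)/6``, ``B3 = u^3/6``; they sum to 1.
    """
    u = np.asarray(u, dtype=float)
    u2, u3 = u * u, u * u * u
    return np.stack(
        [
            (1 - u) ** 3 / 6.0,
            (3 * u3 - 6 * u2 + 4) / 6.0,
            (-3 * u3 + 3 * u2 + 3 * u + 1) / 6.0,
            u3 / 6.0,
        ],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# transform types


@dataclass(frozen=True)
class AffineTransform2D:
    """Affine map ``p -> matrix @ p + translation`` on (x, y) points."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        t = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(m)) <= 1e-8:
            raise ValueError("affine linear part is (near) singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def from_center(
        cls, matrix: np.ndarray, translation: np.ndarray, center: np.ndarray
    ) -> "AffineTransform2D":
        """Affine acting about ``center``: p -> M (p - c) + c + t."""
        m = np.asarray(matrix, dtype=float)
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float)
        return cls(m, c - m @ c + t)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map ``(N, 2)`` (x, y) points."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """self after other: p -> self(other(p))."""
        return AffineTransform2D(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
        )

    @property
    def params(self) -> np.ndarray:
        """6-vector (a11, a12, a21, a22, tx, ty)."""
        return np.concatenate([self.matrix.ravel(), self.translation])

    @classmethod
    def from_params(cls, p: Sequence[float]) -> "AffineTransform2D":
        p = np.asarray(p, dtype=float)
        return cls(p[:4].reshape(2, 2), p[4:6])


def grid_shape_for(
    image_shape: tuple[int, int], spacing: tuple[float, float]
) -> tuple[int, int]:
    """Control grid ``(Gy, Gx)`` large enough that every pixel of an
    ``(M, W)`` image has a full 4x4 support neighborhood (one padding
    control point before the domain and two beyond it)."""
    h, w = image_shape
    dx, dy = spacing
    gx = int(np.floor((w - 1) / dx)) + 4
    gy = int(np.floor((h - 1) / dy)) + 4
    return gy, gx


@dataclass(frozen=True)
class BSplineFFD:
    """Cubic B-spline FFD displacement field.

    ``control_points`` has shape ``(Gy, Gx, 2)`` holding (dx, dy)
    displacements in pixels.  The control point with grid coordinates
    ``(i, j)`` of the tensor-product formula lives at array index
    ``[j + 1, i + 1]`` (one padding point before the image origin).
    """

    control_points: np.ndarray
    spacing: tuple[float, float]

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 3 or cp.shape[2] != 2 or cp.shape[0] < 4 or cp.shape[1] < 4:
            raise ValueError("control_points must have shape (Gy>=4, Gx>=4, 2)")
        dx, dy = self.spacing
        if dx <= 0 or dy <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "control_points", cp)
        object.__setattr__(self, "spacing", (float(dx), float(dy)))

    @classmethod
    def zeros(
        cls, image_shape: tuple[int, int], spacing: float | tuple[float, float]
    ) -> "BSplineFFD":
        if np.isscalar(spacing):
            spacing = (float(spacing), float(spacing))
        gy, gx = grid_shape_for(image_shape, spacing)
        return cls(np.zeros((gy, gx, 2)), spacing)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.control_points.shape[:2]

    def max_domain(self) -> tuple[float, float]:
        """Largest (x, y) with full 4x4 support on this grid."""
        gy, gx = self.grid_shape
        dx, dy = self.spacing
        # need floor(x/dx) + 3 <= gx - 1
        return ((gx - 4 + 1) * dx - 1e-9, (gy - 4 + 1) * dy - 1e-9)

    def displacement(self, x: float, y: float) -> np.ndarray:
        """Displacement (dx, dy) at a single point — the tensor-product sum."""
        dx, dy = self.spacing
        xmax, ymax = self.max_domain()
        if not (0.0 <= x <= xmax and 0.0 <= y <= ymax):
            raise ValueError(f"point ({x}, {y}) outside padded FFD support")
        sx, sy = x / dx, y / dy
        i, j = int(np.floor(sx)) - 1, int(np.floor(sy)) - 1
        u, v = sx - np.floor(sx), sy - np.floor(sy)
        bu = bspline_basis(u)
        bv = bspline_basis(v)
        out = np.zeros(2)
        for l in range(4):
            for m in range(4):
                out += bu[l] * bv[m] * self.control_points[j + m + 1, i + l + 1]
        return out

    def displacement_field(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Dense ``(M, W, 2)`` displacement field over an image domain."""
        bmat = _basis_matrix(image_shape, self.grid_shape, self.spacing)
        gy, gx = self.grid_shape
        flat = bmat @ self.control_points.reshape(gy * gx, 2)
        return flat.reshape(image_shape + (2,))


def bspline_displacement(ffd: BSplineFFD, x: float, y: float) -> np.ndarray:
    """Functional alias for :meth:`BSplineFFD.displacement`."""
    return ffd.displacement(x, y)


_BASIS_CACHE: dict[tuple, sparse.csr_matrix] = {}


def _basis_matrix(image_shape, grid_shape, spacing) -> sparse.csr_matrix:
    """Sparse ``(M*W, Gy*Gx)`` matrix of tensor-product basis weights so
    that ``field = B @ control.reshape(-1, 2)``.  Cached."""
    key = (image_shape, grid_shape, spacing)
    if key in _BASIS_CACHE:
        return _BASIS_CACHE[key]
    h, w = image_shape
    gy, gx = grid_shape
    dx, dy = spacing
    xs = np.arange(w) / dx
    ys = np.arange(h) / dy
    fx = np.floor(xs).astype(int)  # array col index base = fx + l
    fy = np.floor(ys).astype(int)
    bu = bspline_basis(xs - fx)  # (W, 4)
    bv = bspline_basis(ys - fy)  # (H, 4)
    if fx.max() + 3 > gx - 1 or fy.max() + 3 > gy - 1:
        raise ValueError("control grid too small for image domain")
    rows, cols, vals = [], [], []
    pix = np.arange(h * w)
    col_base = (fy[:, None] + np.zeros(w, int)[None, :])  # (H, W) of fy
    for m in range(4):
        for l in range(4):
            c = (fy[:, None] + m) * gx + (fx[None, :] + l)
            v = bv[:, m][:, None] * bu[:, l][None, :]
            rows.append(pix)
            cols.append(c.ravel())
            vals.append(v.ravel())
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(h * w, gy * gx),
    ).tocsr()
    _BASIS_CACHE[key] = mat
    return mat


@dataclass(frozen=True)
class CompositeTransform:
    """Affine part plus optional B-spline FFD, combined additively."""

    global_: AffineTransform2D
    local: BSplineFFD | None = None

    @classmethod
    def identity(cls) -> "CompositeTransform":
        return cls(AffineTransform2D.identity(), None)

    def mapping_field(self, image_shape: tuple[int, int]) -> np.ndarray:
        """``(M, W, 2)`` array of mapped (x, y) coordinates T(x, y)."""
        h, w = image_shape
        xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        pts = np.stack([xx, yy], axis=-1)
        out = pts @ self.global_.matrix.T + self.global_.translation
        if self.local is not None:
            out = out + self.local.displacement_field(image_shape)
        return out

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = self.global_.apply_points(pts)
        if self.local is not None:
            disp = np.array([self.local.displacement(x, y) for x, y in pts])
            out = out + disp
        return out


def apply_transform(t: CompositeTransform, image: ImageFrame) -> ImageFrame:
    """Backward-map resampling: ``output(x, y) = input(T(x, y))``.

    Bilinear interpolation, zero fill outside the input domain.
    """
    coords = t.mapping_field(image.shape)
    warped = _sample(image.pixels, coords)
    return image.with_pixels(np.maximum(warped, 0.0))


def _sample(pixels: np.ndarray, coords_xy: np.ndarray) -> np.ndarray:
    """Bilinear sample at (x, y) coordinate field, zero outside."""
    return ndimage.map_coordinates(
        pixels,
        [coords_xy[..., 1], coords_xy[..., 0]],  # (row, col) = (y, x)
        order=1,
        mode="constant",
        cval=0.0,
    )


def average_transforms(
    transforms: Sequence[CompositeTransform],
) -> CompositeTransform:
    """Parameter-wise arithmetic mean of composite transforms.

    Affine matrices/translations and control-point displacements are
    averaged element-wise ("without any further weighting").  All FFDs
    must share one grid; transforms with no FFD contribute zero local
    displacement.
    """
    if not transforms:
        raise ValueError("need at least one transform")
    mats = np.mean([t.global_.matrix for t in transforms], axis=0)
    trans = np.mean([t.global_.translation for t in transforms], axis=0)
    locals_ = [t.local for t in transforms if t.local is not None]
    local = None
    if locals_:
        ref = locals_[0]
        for f in locals_[1:]:
            if f.grid_shape != ref.grid_shape or f.spacing != ref.spacing:
                raise ValueError("cannot average FFDs on mismatched grids")
        cp = np.sum([f.control_points for f in locals_], axis=0) / len(transforms)
        local = BSplineFFD(cp, ref.spacing)
    return CompositeTransform(AffineTransform2D(mats, trans), local)


# ---------------------------------------------------------------------------
# similarity metrics


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Mutual information of the joint 2D intensity histogram (nats)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    ar = (a.min(), max(a.max(), a.min() + 1e-12))
    br = (b.min(), max(b.max(), b.min() + 1e-12))
    ia = np.clip(((a - ar[0]) / (ar[1] - ar[0]) * bins).astype(int), 0, bins - 1)
    ib = np.clip(((b - br[0]) / (br[1] - br[0]) * bins).astype(int), 0, bins - 1)
    joint = np.bincount(ia * bins + ib, minlength=bins * bins).astype(float)
    joint /= joint.sum()
    pj = joint.reshape(bins, bins)
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    nz = pj > 0
    return float(np.sum(pj[nz] * np.log(pj[nz] / np.outer(pa, pb)[nz])))


def _metric_value(metric: str, fixed: np.ndarray, warped: np.ndarray) -> float:
    """Similarity (higher is better)."""
    if metric == "mi":
        return mutual_information(fixed, warped)
    if metric == "ssd":
        return -float(np.mean((fixed - warped) ** 2))
    if metric == "ncc":
        f = fixed - fixed.mean()
        w = warped - warped.mean()
        denom = np.sqrt((f * f).sum() * (w * w).sum())
        return float((f * w).sum() / denom) if denom > 0 else 0.0
    raise ValueError(f"unknown metric {metric!r}")


def similarity(fixed: ImageFrame, moving: ImageFrame, metric: str = "mi") -> float:
    return _metric_value(metric, fixed.pixels, moving.pixels)


# ---------------------------------------------------------------------------
# registration


@dataclass(frozen=True)
class RegistrationSettings:
    """Deterministic optimizer settings for the registration engine.

    ``affine_levels`` multi-resolution pyramid depth for the affine
    stage (downsampling by 2 per level); ``ffd_spacing`` control-point
    spacing in pixels (default 16 px for 136x136 frames, i.e. roughly
    articulator scale); ``ffd_smooth`` Tikhonov weight on control-point
    second differences keeping the recovered field smooth.
    """

    metric: Literal["mi", "ssd", "ncc"] = "mi"
    metric_smooth: float = 1.2
    affine_levels: int = 3
    affine_maxiter: int = 12
    affine_maxiter_warm: int = 1
    ffd_spacing: float = 16.0
    ffd_maxiter: int = 60
    ffd_levels: int = 2
    ffd_smooth: float = 2e-2

    def scaled(self, factor: float) -> "RegistrationSettings":
        """Settings with the FFD spacing scaled (e.g. for small frames)."""
        import dataclasses

        return dataclasses.replace(self, ffd_spacing=self.ffd_spacing * factor)


_PARAM_SCALE = np.array([0.02, 0.02, 0.02, 0.02, 1.0, 1.0])  # linear, translation


def _pyramid(img: np.ndarray, levels: int, min_size: int = 24) -> list[np.ndarray]:
    """Coarse-to-fine Gaussian pyramid, factor 2 per level.

    Levels smaller than ``min_size`` px are dropped: their metric is
    too poorly sampled to rank candidate transforms reliably.
    """
    out = [img]
    for _ in range(levels - 1):
        sm = ndimage.gaussian_filter(out[-1], 1.0)
        if min(sm[::2, ::2].shape) < min_size:
            break
        out.append(sm[::2, ::2])
    return out[::-1]


def _warp_affine(pixels: np.ndarray, matrix: np.ndarray, trans: np.ndarray,
                 center: np.ndarray) -> np.ndarray:
    h, w = pixels.shape
    xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts = np.stack([xx, yy], axis=-1) - center
    mapped = pts @ matrix.T + center + trans
    return ndimage.map_coordinates(
        pixels, [mapped[..., 1], mapped[..., 0]], order=1, mode="constant", cval=0.0
    )


def _fft_translation(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Integer translation d (x, y) such that ``moving(x + d)`` best
    matches ``fixed(x)``, from the zero-padded (linear, not circular)
    cross-correlation peak; lags beyond a third of the frame are
    ignored as corner artifacts."""
    h, w = fixed.shape
    f = np.zeros((2 * h, 2 * w))
    m = np.zeros((2 * h, 2 * w))
    f[:h, :w] = fixed - fixed.mean()
    m[:h, :w] = moving - moving.mean()
    corr = np.real(np.fft.ifft2(np.fft.fft2(f) * np.conj(np.fft.fft2(m))))
    lags_y = np.r_[0 : h, -h : 0]  # index -> lag for the padded grid
    lags_x = np.r_[0 : w, -w : 0]
    mask_y = np.abs(lags_y) > h // 3
    mask_x = np.abs(lags_x) > w // 3
    corr[mask_y, :] = -np.inf
    corr[:, mask_x] = -np.inf
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    return -np.array([lags_x[ix], lags_y[iy]], dtype=float)


_INIT_SCALES = (0.85, 0.90, 0.95, 1.0, 1.05, 1.10, 1.15)


def _init_affine(
    mv_coarse: np.ndarray, fx_coarse: np.ndarray, to_full: float, metric: str
) -> AffineTransform2D:
    """Deterministic global initializer, evaluated at the coarsest level.

    Tries a small grid of uniform scales; for each, estimates the
    residual translation by FFT cross-correlation and scores the warped
    candidate with the similarity metric.  Returns the best candidate
    as a full-resolution center-anchored affine.
    """
    h, w = fx_coarse.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    best, best_val = AffineTransform2D.identity(), -np.inf
    for s in _INIT_SCALES:
        mat = np.eye(2) * s
        scaled = _warp_affine(mv_coarse, mat, np.zeros(2), center)
        d = _fft_translation(scaled, fx_coarse)
        # compose: mv(s(x - c) + c + s d)
        t = s * d
        cand = _warp_affine(mv_coarse, mat, t, center)
        val = _metric_value(metric, fx_coarse, cand)
        if val > best_val:
            best_val = val
            best = AffineTransform2D.from_center(mat, t * to_full, center * to_full)
    return best


def register_affine(
    moving: ImageFrame,
    fixed: ImageFrame,
    settings: RegistrationSettings | None = None,
    init: AffineTransform2D | None = None,
) -> AffineTransform2D:
    """Estimate the affine maximizing the similarity metric.

    Multi-resolution Powell search over a center-anchored
    parameterization (6 parameters).  With ``init`` given (e.g. the
    previous frame's solution when normalizing a time series) only the
    finest level is searched, warm-started from it.
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share a shape")
    st = settings or RegistrationSettings()
    h, w = fixed.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    # warm starts search only the finest level with a reduced iteration cap
    levels = 1 if init is not None else st.affine_levels
    maxiter = st.affine_maxiter_warm if init is not None else st.affine_maxiter
    xtol = 3e-3 if init is not None else 1e-3
    # light smoothing makes the binned MI metric smooth at subpixel
    # scale; the recovered transform is applied to the original images
    mov_px, fix_px = moving.pixels, fixed.pixels
    if st.metric_smooth > 0:
        mov_px = ndimage.gaussian_filter(mov_px, st.metric_smooth)
        fix_px = ndimage.gaussian_filter(fix_px, st.metric_smooth)
    mov_pyr = _pyramid(mov_px, levels)
    fix_pyr = _pyramid(fix_px, levels)

    if init is None:
        # initialize at ~32 px: fine enough to score candidates reliably
        lvl = int(np.argmin([abs(p.shape[1] - 32) for p in mov_pyr]))
        to_full = w / mov_pyr[lvl].shape[1]
        start = _init_affine(mov_pyr[lvl], fix_pyr[lvl], to_full, st.metric)
    else:
        start = init
    # convert standard form to center-anchored params at full res
    m = start.matrix
    t = start.translation - (center - m @ center)
    z = np.concatenate([(m - np.eye(2)).ravel(), t]) / _PARAM_SCALE

    for lvl, (mv, fx) in enumerate(zip(mov_pyr, fix_pyr)):
        scale = mv.shape[1] / w  # < 1 at coarse levels
        c = center * scale

        def objective(zz):
            p = zz * _PARAM_SCALE
            mat = np.eye(2) + p[:4].reshape(2, 2)
            tr = p[4:6] * scale
            warped = _warp_affine(mv, mat, tr, c)
            return -_metric_value(st.metric, fx, warped)

        # restarting re-seeds Powell's direction set, which otherwise
        # degenerates in the curved scale/translation valley of the metric
        restarts = 1 if init is not None else 3
        best_val = np.inf
        for _ in range(restarts):
            res = optimize.minimize(
                objective,
                z,
                method="Powell",
                options={"maxiter": maxiter, "xtol": xtol, "ftol": 1e-6},
            )
            z = res.x
            if best_val - res.fun < 1e-9:
                break
            best_val = res.fun
        if init is None and lvl == len(mov_pyr) - 1:
            # simplex polish at the finest level tightens the last
            # fraction of a pixel that Powell's line searches leave
            res = optimize.minimize(
                objective,
                z,
                method="Nelder-Mead",
                options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-9},
            )
            if res.fun <= best_val:
                z = res.x

    p = z * _PARAM_SCALE
    mat = np.eye(2) + p[:4].reshape(2, 2)
    return AffineTransform2D.from_center(mat, p[4:6], center)


def register_bspline(
    moving: ImageFrame,
    fixed: ImageFrame,
    spacing: float | None = None,
    settings: RegistrationSettings | None = None,
    affine: AffineTransform2D | None = None,
) -> CompositeTransform:
    """Affine stage then FFD refinement; returns the additive composite.

    The FFD stage minimizes the sum of squared differences between the
    fixed image and the warped moving image (images entering the
    pipeline are histogram-matched first, making SSD appropriate) with
    an analytic gradient through the B-spline basis, plus a small
    first-difference smoothness penalty on the control grid.
    """
    st = settings or RegistrationSettings()
    if spacing is None:
        spacing = st.ffd_spacing
    if spacing < 4:
        raise ValueError("control-point spacing must be >= 4 px")
    if affine is None:
        affine = register_affine(moving, fixed, settings=st)

    h, w = fixed.shape
    ffd = BSplineFFD.zeros((h, w), spacing)
    gy, gx = ffd.grid_shape
    cp = np.zeros((gy, gx, 2))

    levels = max(1, st.ffd_levels)
    for lvl in range(levels - 1, -1, -1):
        f = 2 ** lvl  # downsampling factor for this level
        if f > 1:
            mv = ndimage.gaussian_filter(moving.pixels, f / 2.0)[::f, ::f]
            fx = ndimage.gaussian_filter(fixed.pixels, f / 2.0)[::f, ::f]
        else:
            mv, fx = moving.pixels, fixed.pixels
        cp = _optimize_ffd(
            mv, fx, affine, cp, (spacing / f, spacing / f), (gy, gx), f, st
        )

    return CompositeTransform(affine, BSplineFFD(cp, (spacing, spacing)))


def _optimize_ffd(mov, fix, affine, cp_init, spacing, grid_shape, factor, st):
    """L-BFGS-B over control displacements at one pyramid level.

    ``cp_init`` and the returned control points are in FULL-resolution
    pixel units; coordinates at this level are scaled by 1/factor.
    """
    h, w = fix.shape
    gy, gx = grid_shape
    bmat = _basis_matrix((h, w), grid_shape, spacing)
    bmat_t = bmat.T.tocsr()

    xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts = np.stack([xx * factor, yy * factor], axis=-1)  # full-res coords
    base = (pts @ affine.matrix.T + affine.translation) / factor  # level coords

    grad_y, grad_x = np.gradient(mov)
    n = fix.size
    lam = st.ffd_smooth

    def fun(flat):
        cp = flat.reshape(gy * gx, 2)
        disp = (bmat @ cp) / factor  # full-res displacement -> level coords
        sx = base[..., 0] + disp[:, 0].reshape(h, w)
        sy = base[..., 1] + disp[:, 1].reshape(h, w)
        warped = ndimage.map_coordinates(mov, [sy, sx], order=1, mode="constant")
        r = warped - fix
        gxs = ndimage.map_coordinates(grad_x, [sy, sx], order=1, mode="constant")
        gys = ndimage.map_coordinates(grad_y, [sy, sx], order=1, mode="constant")
        val = float(np.mean(r * r))
        gx_flat = (2.0 / n / factor) * (bmat_t @ (r * gxs).ravel())
        gy_flat = (2.0 / n / factor) * (bmat_t @ (r * gys).ravel())
        grad = np.stack([gx_flat, gy_flat], axis=-1)
        # first-difference smoothness on the control grid
        cpg = cp.reshape(gy, gx, 2)
        dyd = np.diff(cpg, axis=0)
        dxd = np.diff(cpg, axis=1)
        val += lam * (np.mean(dyd ** 2) + np.mean(dxd ** 2))
        sg = np.zeros_like(cpg)
        sg[1:, :] += 2 * lam * dyd / dyd.size
        sg[:-1, :] -= 2 * lam * dyd / dyd.size
        sg[:, 1:] += 2 * lam * dxd / dxd.size
        sg[:, :-1] -= 2 * lam * dxd / dxd.size
        return val, (grad + sg.reshape(gy * gx, 2)).ravel()

    res = optimize.minimize(
        fun,
        cp_init.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": st.ffd_maxiter, "ftol": 1e-10, "gtol": 1e-8},
    )
    return res.x.reshape(gy, gx, 2)


def mean_endpoint_error(
    t1: CompositeTransform, t2: CompositeTransform, image_shape: tuple[int, int]
) -> float:
    """Mean over pixels of |T1(x,y) - T2(x,y)| in pixels."""
    d = t1.mapping_field(image_shape) - t2.mapping_field(image_shape)
    return float(np.mean(np.hypot(d[..., 0], d[..., 1])))
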
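"""Transform model, B-spline evaluation, warping and registration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtatlas.core import ImageFrame
from vtatlas.registration import (
    AffineTransform2D,
    BSplineFFD,
    CompositeTransform,
    RegistrationSettings,
    apply_transform,
    average_transforms,
    bspline_basis,
    bspline_displacement,
    mean_endpoint_error,
    register_affine,
    register_bspline,
)

SETTINGS_64 = RegistrationSettings(ffd_spacing=8.0)


class TestBasis:
    @given(st.floats(0.0, 1.0, exclude_max=True))
    @settings(max_examples=200, derandomize=True)
    def test_partition_of_unity(self, u):
        assert abs(bspline_basis(u).sum() - 1.0) < 1e-12

    def test_basis_values_at_zero(self):
        b = bspline_basis(0.0)
        np.testing.assert_allclose(b, [1 / 6, 4 / 6, 1 / 6, 0.0], atol=1e-15)


class TestFFDEvaluation:
    def test_zero_grid_gives_zero_displacement(self):
        ffd = BSplineFFD.zeros((40, 40), 8)
        np.testing.assert_array_equal(bspline_displacement(ffd, 13.0, 27.0), [0, 0])

    def test_constant_grid_gives_constant_field(self):
        ffd = BSplineFFD.zeros((40, 40), 8)
        ffd = BSplineFFD(ffd.control_points + np.array([1.5, -2.0]), ffd.spacing)
        field = ffd.displacement_field((40, 40))
        np.testing.assert_allclose(field[..., 0], 1.5, atol=1e-12)
        np.testing.assert_allclose(field[..., 1], -2.0, atol=1e-12)

    def test_single_node_weight_is_four_ninths(self):
        # at a grid node (u=v=0) the active control point takes basis
        # role l=m=1 with weight (4/6)^2
        ffd = BSplineFFD.zeros((40, 40), 8)
        cp = ffd.control_points.copy()
        cp[2, 2] = [1.0, 0.0]
        ffd = BSplineFFD(cp, ffd.spacing)
        np.testing.assert_allclose(
            ffd.displacement(8.0, 8.0), [16 / 36, 0.0], atol=1e-12
        )

    def test_scalar_and_field_evaluations_agree(self, rng):
        ffd = BSplineFFD.zeros((33, 47), (7.0, 9.0))
        ffd = BSplineFFD(rng.normal(0, 1, ffd.control_points.shape), ffd.spacing)
        field = ffd.displacement_field((33, 47))
        for x, y in [(0, 0), (46, 32), (13, 21), (31, 7)]:
            np.testing.assert_allclose(
                field[y, x], ffd.displacement(float(x), float(y)), atol=1e-12
            )

    def test_outside_support_rejected(self):
        ffd = BSplineFFD.zeros((40, 40), 8)
        with pytest.raises(ValueError):
            ffd.displacement(-1.0, 5.0)
        with pytest.raises(ValueError):
            ffd.displacement(5.0, 400.0)


class TestAgainstSimpleITK:
    def test_ffd_evaluation_matches_sitk_bspline_transform(self, rng):
        """The tensor-product evaluation agrees with SimpleITK's
        BSplineTransform on identical coefficients (independent oracle)."""
        sitk = pytest.importorskip("SimpleITK")
        spacing = 8.0
        base = BSplineFFD.zeros((40, 40), spacing)
        cp = rng.normal(0, 2, base.control_points.shape)
        ffd = BSplineFFD(cp, (spacing, spacing))
        gy, gx = ffd.grid_shape
        t = sitk.BSplineTransform(2, 3)
        t.SetTransformDomainOrigin((0.0, 0.0))
        t.SetTransformDomainDirection((1.0, 0.0, 0.0, 1.0))
        t.SetTransformDomainPhysicalDimensions(
            ((gx - 3) * spacing, (gy - 3) * spacing)
        )
        t.SetTransformDomainMeshSize((gx - 3, gy - 3))
        t.SetParameters(tuple(np.concatenate([cp[..., 0].ravel(), cp[..., 1].ravel()])))
        for x, y in [(0.0, 0.0), (5.3, 7.7), (20.0, 16.0), (33.2, 9.9), (36.9, 36.9)]:
            theirs = np.array(t.TransformPoint((x, y))) - np.array([x, y])
            np.testing.assert_allclose(ffd.displacement(x, y), theirs, atol=1e-9)


class TestApplyTransform:
    def test_identity_is_exact(self, random_frame):
        out = apply_transform(CompositeTransform.identity(), random_frame)
        np.testing.assert_allclose(out.pixels, random_frame.pixels, atol=1e-9)

    def test_integer_translation_shifts_with_zero_fill(self, random_frame):
        t = CompositeTransform(
            AffineTransform2D(np.eye(2), np.array([3.0, 0.0])), None
        )
        out = apply_transform(t, random_frame)
        # output(x) = input(x+3): content moves 3 columns left, right edge zero
        np.testing.assert_allclose(
            out.pixels[:, :-3], random_frame.pixels[:, 3:], atol=1e-12
        )
        np.testing.assert_array_equal(out.pixels[:, -3:], 0.0)

    def test_half_pixel_shift_on_linear_ramp(self):
        ramp = np.tile(np.arange(16.0), (8, 1))
        t = CompositeTransform(
            AffineTransform2D(np.eye(2), np.array([0.5, 0.0])), None
        )
        out = apply_transform(t, ImageFrame(ramp))
        np.testing.assert_allclose(out.pixels[:, :-1], ramp[:, :-1] + 0.5, atol=1e-9)


class TestAverageTransforms:
    def test_single_transform_is_identity_operation(self):
        t = CompositeTransform(
            AffineTransform2D(np.array([[1.1, 0], [0, 0.9]]), np.array([2.0, 1.0])),
            None,
        )
        avg = average_transforms([t])
        np.testing.assert_allclose(avg.global_.params, t.global_.params)

    def test_translations_average_linearly(self):
        t1 = CompositeTransform(AffineTransform2D(np.eye(2), np.array([2.0, 0.0])))
        t2 = CompositeTransform(AffineTransform2D(np.eye(2), np.array([0.0, 0.0])))
        avg = average_transforms([t1, t2])
        np.testing.assert_allclose(avg.global_.translation, [1.0, 0.0])

    def test_opposite_ffd_fields_cancel(self, rng):
        base = BSplineFFD.zeros((32, 32), 8)
        cp = rng.normal(0, 2, base.control_points.shape)
        f1 = CompositeTransform(AffineTransform2D.identity(), BSplineFFD(cp, base.spacing))
        f2 = CompositeTransform(
            AffineTransform2D.identity(), BSplineFFD(-cp, base.spacing)
        )
        avg = average_transforms([f1, f2])
        np.testing.assert_allclose(avg.local.control_points, 0.0, atol=1e-12)

    def test_permutation_invariance(self, rng):
        ts = []
        for _ in range(3):
            base = BSplineFFD.zeros((32, 32), 8)
            ts.append(
                CompositeTransform(
                    AffineTransform2D(
                        np.eye(2) + rng.normal(0, 0.01, (2, 2)), rng.normal(0, 1, 2)
                    ),
                    BSplineFFD(rng.normal(0, 1, base.control_points.shape), base.spacing),
                )
            )
        a = average_transforms(ts)
        b = average_transforms(ts[::-1])
        np.testing.assert_allclose(a.global_.params, b.global_.params, atol=1e-12)
        np.testing.assert_allclose(
            a.local.control_points, b.local.control_points, atol=1e-12
        )

    def test_mismatched_grids_rejected(self):
        f1 = CompositeTransform(
            AffineTransform2D.identity(), BSplineFFD.zeros((32, 32), 8)
        )
        f2 = CompositeTransform(
            AffineTransform2D.identity(), BSplineFFD.zeros((32, 32), 16)
        )
        with pytest.raises(ValueError):
            average_transforms([f1, f2])


class TestRegistration:
    def test_self_registration_is_identity(self, phantom_frame):
        t = register_affine(phantom_frame, phantom_frame, settings=SETTINGS_64)
        assert np.abs(t.translation).max() < 0.1
        np.testing.assert_allclose(t.matrix, np.eye(2), atol=0.01)

    def test_translation_recovery(self, phantom_frame):
        true = AffineTransform2D(np.eye(2), np.array([5.0, -3.0]))
        moved = apply_transform(CompositeTransform(true), phantom_frame)
        rec = register_affine(moved, phantom_frame, settings=SETTINGS_64)
        err = mean_endpoint_error(
            CompositeTransform(rec), CompositeTransform(true.inverse()), (64, 64)
        )
        assert err < 0.5

    def test_scale_recovery(self, phantom_frame):
        c = np.array([31.5, 31.5])
        true = AffineTransform2D.from_center(np.eye(2) * 1.1, np.zeros(2), c)
        moved = apply_transform(CompositeTransform(true), phantom_frame)
        rec = register_affine(moved, phantom_frame, settings=SETTINGS_64)
        # recovered scale within 2 %
        assert abs(np.sqrt(abs(np.linalg.det(rec.matrix))) - 1 / 1.1) < 0.02 / 1.1

    def test_self_bspline_registration_is_near_zero(self, phantom_frame):
        t = register_bspline(phantom_frame, phantom_frame, settings=SETTINGS_64)
        assert np.abs(t.local.control_points).max() < 0.5

    def test_known_ffd_bump_recovered(self, phantom_frame):
        ffd = BSplineFFD.zeros((64, 64), 8)
        cp = ffd.control_points.copy()
        gy, gx, _ = cp.shape
        ys, xs = np.mgrid[0:gy, 0:gx]
        cp[..., 0] = 2.5 * np.exp(-((xs - gx / 2) ** 2 + (ys - gy / 2) ** 2) / 6.0)
        cp[..., 1] = -2.0 * np.exp(-((xs - gx / 3) ** 2 + (ys - gy / 2) ** 2) / 6.0)
        true = CompositeTransform(AffineTransform2D.identity(), BSplineFFD(cp, (8, 8)))
        warped = apply_transform(true, phantom_frame)
        rec = register_bspline(phantom_frame, warped, settings=SETTINGS_64)
        assert mean_endpoint_error(rec, true, (64, 64)) < 1.0

    def test_minimum_spacing_enforced(self, phantom_frame):
        with pytest.raises(ValueError):
            register_bspline(phantom_frame, phantom_frame, spacing=2.0)


class TestPhantomGroundTruth:
    def test_inter_speaker_affine_recovered(self):
        from vtatlas.phantom import generate_cohort

        ds = generate_cohort(
            n_speakers=2, cv_list=("tu",), planes=("M",), image_size=136, seed=3
        )
        rec = register_bspline(ds.silence("SP1", "M"), ds.silence("SP2", "M"))
        true = CompositeTransform(ds.true_pair_affine("SP1", "SP2"))
        assert mean_endpoint_error(rec, true, (136, 136)) < 1.0
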
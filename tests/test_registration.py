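"""Rigid recovery, deformable recovery, inversion and warping contracts."""

import math

import numpy as np
import pytest

from doseaccum.core import GridGeometry, ImageVolume, StructureMask, resample
from doseaccum.registration import (
    ConvergenceError,
    DisplacementField,
    GffdParams,
    InvertibilityError,
    RegistrationError,
    RigidTransform,
    compose_rigid_into_field,
    composition_residual,
    gffd_similarity,
    invert_field,
    register_gffd,
    register_rigid,
    resample_through_rigid,
    warp,
)
from doseaccum.synthetic import DegradationParams, build_phantom, simulate_course

from conftest import SMALL_CBCT_GEOMETRY, short_course, small_phantom_params


def smooth_field(geometry, amplitude=6.0):
    """A smooth, comfortably invertible synthetic displacement field."""
    pts = geometry.world_points()
    ext = geometry.extent
    v = np.zeros(geometry.shape + (3,))
    phase = 2 * np.pi * (pts - geometry.origin_arr) / (ext + 1e-9)
    v[..., 0] = amplitude * np.sin(phase[..., 0]) * np.cos(phase[..., 1])
    v[..., 1] = 0.6 * amplitude * np.cos(phase[..., 2])
    v[..., 2] = 0.4 * amplitude * np.sin(phase[..., 1])
    return DisplacementField(geometry, v)


class TestRigid:
    def test_identity_recovered(self, small_phantom):
        ct, _ = small_phantom
        r = register_rigid(ct, ct)
        assert np.abs(r.translation).max() < 0.2
        assert math.degrees(np.abs(r.rotation).max()) < 0.2

    def test_known_translation_recovered(self, small_phantom):
        ct, _ = small_phantom
        true = RigidTransform((5.0, 0.0, 0.0), center=tuple(ct.geometry.center))
        moved = resample_through_rigid(ct, ct.geometry, true)
        r = register_rigid(ct, moved)
        # registering the pre-transformed image recovers the same mapping
        assert abs(r.translation[0] - (-5.0)) < 0.5
        assert abs(r.translation[1]) < 0.5 and abs(r.translation[2]) < 0.5

    def test_known_rotation_recovered(self, phantom):
        # needs the default-resolution grid: a 3 degree rotation moves the
        # periphery by ~4 mm, which the compact 5 mm grid cannot resolve
        ct, _ = phantom
        true = RigidTransform(
            (0, 0, 0), (0, 0, math.radians(3.0)), tuple(ct.geometry.center)
        )
        moved = resample_through_rigid(ct, ct.geometry, true)
        r = register_rigid(ct, moved)
        assert abs(math.degrees(r.rotation[2]) - (-3.0)) < 0.5

    def test_constant_image_rejected(self):
        g = GridGeometry((16, 16, 16), (2, 2, 2))
        flat = ImageVolume(g, np.zeros(g.shape))
        with pytest.raises(RegistrationError):
            register_rigid(flat, flat)


@pytest.fixture(scope="module")
def deformed_week():
    """A corrupted weekly study on the compact grid, plus its phantom."""
    ct, masks = build_phantom(small_phantom_params(), seed=2)
    course = short_course(seed=2, setup_sigma_mm=0.0, setup_sigma_deg=0.0)
    studies = simulate_course(ct, masks, course, DegradationParams(seed=2))
    return ct, masks, studies[-1]


class TestGffd:
    def test_identity_registration_is_zero_field(self, small_phantom):
        ct, _ = small_phantom
        field = register_gffd(ct, ct, GffdParams())
        vox = min(ct.geometry.spacing)
        assert (field.magnitude() / vox).mean() < 0.1

    def test_known_warp_recovery_within_one_voxel(self, deformed_week):
        ct, masks, study = deformed_week
        moving = resample(ct, study.cbct.geometry)
        field = register_gffd(study.cbct, moving, GffdParams())
        err = np.linalg.norm(field.vectors - study.gt_field.vectors, axis=-1)
        body = study.gt_masks["BODY"].values
        vox = min(study.cbct.geometry.spacing)
        assert err[body].mean() < vox

    def test_returned_field_scores_no_worse_than_zero(self, deformed_week):
        # single-level run: the accept-only-improving rule guarantees the
        # bound exactly; pyramid upsampling between levels would not
        ct, _, study = deformed_week
        moving = resample(ct, study.cbct.geometry)
        params = GffdParams(
            shrink_factors=(1,), iterations=(30,), gradient_sigma_mm=(3.0,),
            eps_kmed=(8.0,), fluid_sigma_mm=(6.0,),
        )
        field = register_gffd(study.cbct, moving, params)
        s_field = gffd_similarity(study.cbct, moving, field, params)
        s_zero = gffd_similarity(
            study.cbct, moving, DisplacementField.zero(field.geometry), params
        )
        assert s_field <= s_zero

    def test_intensity_offset_invariance(self, deformed_week):
        # gradients ignore constant offsets, so +100 HU changes nothing
        ct, _, study = deformed_week
        moving = resample(ct, study.cbct.geometry)
        shifted = ImageVolume(
            moving.geometry, moving.values + 100.0, modality=moving.modality
        )
        f1 = register_gffd(study.cbct, moving, GffdParams())
        f2 = register_gffd(study.cbct, shifted, GffdParams())
        body = study.gt_masks["BODY"].values
        vox = min(study.cbct.geometry.spacing)
        tre1 = np.linalg.norm(f1.vectors - study.gt_field.vectors, axis=-1)[body].mean()
        tre2 = np.linalg.norm(f2.vectors - study.gt_field.vectors, axis=-1)[body].mean()
        assert abs(tre1 - tre2) / vox < 0.2

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_recovery_across_corruption_seeds(self, seed):
        ct, masks = build_phantom(small_phantom_params(), seed=seed)
        course = short_course(seed=seed)
        study = simulate_course(ct, masks, course, DegradationParams(seed=seed))[-1]
        rigid = register_rigid(study.cbct, ct)
        aligned = resample_through_rigid(ct, study.cbct.geometry, rigid)
        v = register_gffd(study.cbct, aligned, GffdParams())
        total = compose_rigid_into_field(v, rigid)
        err = np.linalg.norm(total.vectors - study.gt_field.vectors, axis=-1)
        body = study.gt_masks["BODY"].values
        vox = min(study.cbct.geometry.spacing)
        assert err[body].mean() < vox


class TestInvertField:
    def test_zero_field_inverts_to_zero(self):
        g = GridGeometry((12, 12, 12), (2.5, 2.5, 2.5))
        inv = invert_field(DisplacementField.zero(g))
        assert np.abs(inv.vectors).max() == 0.0

    def test_constant_translation_exact_negation(self):
        g = GridGeometry((12, 12, 12), (2.5, 2.5, 2.5))
        t = np.array([3.0, -2.0, 1.0])
        field = DisplacementField(g, np.broadcast_to(t, g.shape + (3,)).copy())
        inv = invert_field(field, tol=1e-9)
        assert np.abs(inv.vectors - (-t)).max() < 1e-8

    def test_smooth_field_composition_residual_small(self):
        g = GridGeometry((24, 24, 24), (4.0, 4.0, 4.0))
        field = smooth_field(g, amplitude=5.0)
        inv = invert_field(field, tol=0.01, max_iter=200)
        res = composition_residual(field, inv)
        interior = res[3:-3, 3:-3, 3:-3]
        assert interior.mean() / 4.0 < 0.1  # voxels

    def test_folding_field_rejected(self):
        g = GridGeometry((16, 4, 4), (2.0, 2.0, 2.0))
        v = np.zeros(g.shape + (3,))
        # displacement gradient < -1 folds space
        v[..., 0] = -3.0 * g.world_points()[..., 0]
        with pytest.raises(InvertibilityError):
            invert_field(DisplacementField(g, v))

    def test_nonconvergence_raises(self):
        g = GridGeometry((16, 16, 16), (2.0, 2.0, 2.0))
        field = smooth_field(g, amplitude=1.5)
        with pytest.raises(ConvergenceError):
            invert_field(field, tol=1e-12, max_iter=1)

    def test_inverse_on_target_geometry(self):
        g = GridGeometry((20, 20, 20), (3.0, 3.0, 3.0))
        target = GridGeometry((15, 15, 15), (4.0, 4.0, 4.0))
        t = np.array([2.0, 0.0, -1.0])
        field = DisplacementField(g, np.broadcast_to(t, g.shape + (3,)).copy())
        inv = invert_field(field, tol=1e-9, target=target)
        assert inv.geometry == target
        assert np.abs(inv.vectors - (-t)).max() < 1e-8


class TestWarp:
    def test_zero_field_equals_resample(self, small_phantom):
        ct, _ = small_phantom
        field = DisplacementField.zero(SMALL_CBCT_GEOMETRY)
        out = warp(ct, field)
        ref = resample(ct, SMALL_CBCT_GEOMETRY)
        np.testing.assert_allclose(out.values, ref.values, atol=1e-4)

    def test_constant_source_constant_output(self):
        g = GridGeometry((16, 16, 16), (3.0, 3.0, 3.0))
        const = ImageVolume(g, np.full(g.shape, 123.0))
        out = warp(const, smooth_field(g, amplitude=3.0))
        interior = out.values[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(interior, 123.0, atol=1e-3)

    def test_round_trip_through_inverse_is_small(self, small_phantom):
        # the bound applies to a smooth image; interpolation of the raw
        # piecewise-constant phantom is limited by its sharp edges instead
        from scipy.ndimage import gaussian_filter

        raw, _ = small_phantom
        ct = ImageVolume(raw.geometry, gaussian_filter(raw.values, 1.0))
        field = smooth_field(ct.geometry, amplitude=5.0)
        inv = invert_field(field, tol=0.01, max_iter=200)
        back = warp(warp(ct, field), inv)
        interior = (slice(4, -4),) * 3
        dyn = float(np.ptp(ct.values))
        err = np.abs(back.values[interior] - ct.values[interior]).mean()
        assert err / dyn < 0.02

    def test_geometry_mismatch_raises(self, small_phantom):
        ct, masks = small_phantom
        bad = DisplacementField.zero(GridGeometry((4, 4, 4), (1, 1, 1)))
        m = masks["PG_L"]
        out = warp(m, bad)  # warping onto the field's grid is the contract
        assert out.geometry == bad.geometry


class TestComposeRigid:
    def test_compose_matches_sequential_application(self, small_phantom):
        ct, _ = small_phantom
        g = SMALL_CBCT_GEOMETRY
        rigid = RigidTransform((2.0, -1.0, 0.5), (0.01, 0.0, -0.02), tuple(g.center))
        field = smooth_field(g, amplitude=3.0)
        total = compose_rigid_into_field(field, rigid)
        a = warp(ct, total)
        aligned = resample_through_rigid(ct, g, rigid)
        # sequential: first deformable sample of the rigidly-resampled image
        b = warp(aligned, field)
        interior = (slice(3, -3),) * 3
        assert np.abs(a.values[interior] - b.values[interior]).mean() < 25.0
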
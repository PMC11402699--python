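"""Segmentation, NMI registration, osteotomy cropping, density mapping."""

import dataclasses

import numpy as np
import pytest

from phalanxfem import imaging
from phalanxfem.images import Mask, VoxelImage
from phalanxfem.imaging import (
    DensityCalibration,
    crop_to_osteotomy,
    density_to_modulus,
    map_density,
    normalized_mutual_information,
    register_rigid_nmi,
    resample_to,
    segment_bone,
)
from phalanxfem.synthdata import PhantomSpec, annulus_volume, make_phalanx_phantom
from phalanxfem.transforms import RigidTransform


class TestSegmentation:
    def test_phantom_mask_is_cortex_only(self, coarse_phantom):
        # smoothing off: the clean phantom needs no closing and the mask is
        # then the exact voxel-centre classification of the cortex
        mask = segment_bone(coarse_phantom.image, close_radius=0)
        assert mask.volume_mm3() == pytest.approx(
            annulus_volume(coarse_phantom.spec), rel=0.02
        )
        # marrow (100 HU) must not be included
        marrow = np.abs(coarse_phantom.image.values - 100.0) < 1.0
        assert not (mask.values & marrow).any()

    def test_default_closing_only_grows_the_mask_slightly(self, coarse_phantom):
        raw = segment_bone(coarse_phantom.image, close_radius=0)
        closed = segment_bone(coarse_phantom.image)
        assert (raw.values & ~closed.values).sum() == 0  # closing never removes
        assert (closed.count() - raw.count()) / raw.count() < 0.05

    def test_all_below_threshold_raises(self):
        img = VoxelImage(np.full((8, 8, 8), 399.0), 1.0, (0, 0, 0))
        with pytest.raises(ValueError, match="400"):
            segment_bone(img)

    def test_bounds_are_inclusive(self):
        img = VoxelImage(np.full((8, 8, 8), 400.0), 1.0, (0, 0, 0))
        assert segment_bone(img).values.all()
        img = VoxelImage(np.full((8, 8, 8), 4000.0), 1.0, (0, 0, 0))
        assert segment_bone(img).values.all()

    def test_idempotent_on_binary_reinput(self, coarse_phantom):
        mask = segment_bone(coarse_phantom.image)
        as_hu = VoxelImage(
            np.where(mask.values, 1000.0, 0.0), mask.spacing, mask.origin
        )
        again = segment_bone(as_hu)
        assert np.array_equal(again.values, mask.values)


class TestRegistration:
    def test_self_registration_is_identity(self, coarse_phantom):
        img = coarse_phantom.image
        res = register_rigid_nmi(img, img, finest_spacing=0.5)
        assert res.transform.angle_deg() < 0.5
        assert np.abs(res.transform.translation).max() < 0.25 * img.spacing.max()
        assert res.nmi >= res.initial_nmi

    def test_known_translation_recovered(self):
        spec = PhantomSpec(voxel_size=0.4, noise_sd=20.0, seed=3, margin=1.2)
        img = make_phalanx_phantom(spec).image
        G = RigidTransform(np.eye(3), (1.0, -0.6, 0.4))
        moved = resample_to(img, img, G)
        res = register_rigid_nmi(moved, img)
        resid = res.transform.compose(G)  # should be ~identity
        np.testing.assert_array_less(np.abs(resid.translation), 0.25 * spec.voxel_size)

    def test_rotation_round_trip_on_asymmetric_image(self):
        # the plain phantom is rotationally symmetric about its axis, which
        # leaves that rotation unobservable; add an off-axis rod to break it
        spec = PhantomSpec(voxel_size=0.4, noise_sd=0.0, margin=1.5)
        model = make_phalanx_phantom(spec)
        img = model.image
        x, y, z = img.center_grid()
        rod = (
            (np.abs(y[None, :, None] - 3.0) < 1.0)
            & (np.abs(z[None, None, :] - 3.0) < 1.0)
            & (x[:, None, None] > 2.0)
        )
        img.values = np.where(rod, 2500.0, img.values)
        G = RigidTransform.from_axis_angle((1.0, 0.3, 0.2), 2.0, (0.8, -0.5, 0.3))
        moved = resample_to(img, img, G)
        res = register_rigid_nmi(moved, img)
        resid = res.transform.compose(G)
        assert resid.angle_deg() < 0.5
        np.testing.assert_array_less(np.abs(resid.translation), 0.25 * 0.4)

    def test_result_never_worse_than_initial(self, coarse_phantom):
        img = coarse_phantom.image
        res = register_rigid_nmi(img, img, finest_spacing=1.0)
        assert res.nmi >= res.initial_nmi

    def test_nmi_of_identical_samples_is_maximal(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=5000)
        assert normalized_mutual_information(a, a) > normalized_mutual_information(
            a, rng.normal(size=5000)
        )

    def test_too_few_bins_rejected(self, coarse_phantom):
        with pytest.raises(ValueError):
            register_rigid_nmi(coarse_phantom.image, coarse_phantom.image, bins=4)


class TestOsteotomyCrop:
    def test_crop_reproduces_generator_ground_truth(self, coarse_phantom):
        intact = make_phalanx_phantom(
            dataclasses.replace(coarse_phantom.spec, gap_size=0.0)
        )
        mask = segment_bone(intact.image, close_radius=0)
        prox, dist = crop_to_osteotomy(
            mask, coarse_phantom.gap_center, coarse_phantom.gap_normal,
            coarse_phantom.spec.gap_size,
        )
        assert np.array_equal(prox.values, coarse_phantom.proximal_mask.values)
        assert np.array_equal(dist.values, coarse_phantom.distal_mask.values)

    def test_zero_gap_partitions_exactly(self, coarse_phantom):
        mask = coarse_phantom.cortex_mask()
        prox, dist = crop_to_osteotomy(mask, (0, 0, 0), (1, 0, 0), 0.0)
        assert np.array_equal(prox.values | dist.values, mask.values)
        assert not (prox.values & dist.values).any()

    def test_flipped_normal_swaps_labels(self, coarse_phantom):
        mask = coarse_phantom.cortex_mask()
        p1, d1 = crop_to_osteotomy(mask, (0, 0, 0), (1, 0, 0), 3.0)
        p2, d2 = crop_to_osteotomy(mask, (0, 0, 0), (-1, 0, 0), 3.0)
        assert np.array_equal(p1.values, d2.values)
        assert np.array_equal(d1.values, p2.values)
        assert np.array_equal(p1.values | d1.values, p2.values | d2.values)

    def test_empty_fragment_raises(self, coarse_phantom):
        mask = coarse_phantom.cortex_mask()
        with pytest.raises(ValueError, match="empty"):
            crop_to_osteotomy(mask, (50.0, 0, 0), (1, 0, 0), 3.0)


class TestDensityMapping:
    def test_identity_calibration_passes_hu_through(self, coarse_phantom):
        cal = DensityCalibration()
        mask = coarse_phantom.cortex_mask()
        rho = map_density(coarse_phantom.image, mask, cal)
        assert rho.values[mask.values].min() == rho.values[mask.values].max() == 1600.0
        assert (rho.values[~mask.values] == 0).all()

    def test_negative_density_clamped(self):
        cal = DensityCalibration(hu_intercept=-500.0)
        img = VoxelImage(np.full((4, 4, 4), 100.0), 1.0, (0, 0, 0))
        mask = Mask.like(img, np.ones((4, 4, 4), dtype=bool))
        assert (map_density(img, mask, cal).values == 0).all()

    def test_modulus_power_law(self):
        cal = DensityCalibration(
            modulus_coefficient=1.0, density_reference=1.0, modulus_exponent=1.0,
            min_modulus=0.0,
        )
        assert density_to_modulus(123.0, cal) == pytest.approx(123.0)
        cal2 = DensityCalibration(modulus_exponent=2.0)
        assert density_to_modulus(800.0, cal2) * 4 == pytest.approx(
            density_to_modulus(1600.0, cal2)
        )

    def test_zero_density_hits_floor(self):
        cal = DensityCalibration()
        assert density_to_modulus(0.0, cal) == cal.min_modulus
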
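"""Generator ground truth: phantom geometry, plate mesh, markers, curves."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from phalanxfem import material, synthdata
from phalanxfem.kinematics import fit_rigid_transform
from phalanxfem.synthdata import (
    PhantomSpec,
    PlateSpec,
    StressStrainCurve,
    annulus_volume,
    make_dogbone_curve,
    make_marker_trajectory,
    make_phalanx_phantom,
    make_plate,
    plate_solid_volume,
)
from phalanxfem.transforms import RigidTransform


class TestPhantom:
    def test_no_gap_gives_single_connected_cortex(self):
        spec = PhantomSpec(gap_size=0.0, voxel_size=0.3)
        model = make_phalanx_phantom(spec)
        cortex = (model.image.values >= 400) & (model.image.values <= 4000)
        _, n = ndimage.label(cortex, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_gap_is_exact_number_of_empty_planes(self):
        spec = PhantomSpec(gap_size=3.0, voxel_size=0.5)
        model = make_phalanx_phantom(spec)
        occupied = (model.proximal_mask.values | model.distal_mask.values).any(axis=(1, 2))
        lo = model.proximal_mask.values.any(axis=(1, 2)).nonzero()[0].max()
        hi = model.distal_mask.values.any(axis=(1, 2)).nonzero()[0].min()
        assert hi - lo - 1 == 6  # 3 mm gap / 0.5 mm voxels
        assert not occupied[lo + 1:hi].any()

    def test_cortex_voxel_count_matches_analytic_annulus(self, coarse_phantom):
        spec = coarse_phantom.spec
        in_band = (coarse_phantom.image.values >= 400) & (coarse_phantom.image.values <= 4000)
        vol = in_band.sum() * coarse_phantom.image.voxel_volume()
        assert vol == pytest.approx(annulus_volume(spec), rel=0.02)

    def test_masks_partition_the_segmentation_band(self, coarse_phantom):
        in_band = (coarse_phantom.image.values >= 400) & (coarse_phantom.image.values <= 4000)
        union = coarse_phantom.proximal_mask.values | coarse_phantom.distal_mask.values
        assert np.array_equal(in_band, union)
        assert not (coarse_phantom.proximal_mask.values & coarse_phantom.distal_mask.values).any()

    def test_unresolvable_cortex_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            PhantomSpec(voxel_size=2.0, cortical_thickness=1.5)

    def test_invalid_contrast_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(marrow_hu=500.0)

    def test_seeded_noise_is_reproducible(self):
        spec = PhantomSpec(voxel_size=0.5, noise_sd=30.0, seed=42)
        a = make_phalanx_phantom(spec).image.values
        b = make_phalanx_phantom(dataclasses.replace(spec)).image.values
        assert np.array_equal(a, b)


class TestPlate:
    def test_hole_centers_match_surgical_guide(self):
        assert np.allclose(PlateSpec().hole_centers_x(), [-10.0, -5.0, 5.0, 10.0])

    def test_four_symmetric_hole_sets(self):
        plate = make_plate(PlateSpec(), edge=0.5)
        sets = [plate.mesh.node_sets[f"hole_{i}"] for i in range(1, 5)]
        assert all(len(s) > 0 for s in sets)
        # mirror x -> -x maps hole_1 <-> hole_4 and hole_2 <-> hole_3
        for a, b in [(0, 3), (1, 2)]:
            pa = plate.mesh.nodes[sets[a]].copy()
            pa[:, 0] *= -1
            pb = plate.mesh.nodes[sets[b]]
            assert_same_point_set(pa, pb)
        # mirror y -> -y maps each hole set onto itself
        for s in sets:
            pa = plate.mesh.nodes[s].copy()
            pa[:, 1] *= -1
            assert_same_point_set(pa, plate.mesh.nodes[s])

    def test_mesh_volume_matches_prism_minus_holes(self):
        spec = PlateSpec()
        plate = make_plate(spec, edge=0.25)
        assert plate.mesh.volume() == pytest.approx(plate_solid_volume(spec), rel=0.02)

    def test_divots_on_top_surface_between_holes(self):
        plate = make_plate(PlateSpec(), edge=0.5)
        for d, sgn in [(plate.divot_proximal, -1), (plate.divot_distal, +1)]:
            assert d[2] == pytest.approx(plate.spec.thickness)
            assert sgn * d[0] == pytest.approx(7.5)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            PlateSpec(length=18.0)  # outer holes fall outside
        with pytest.raises(ValueError):
            PlateSpec(hole_spacing=1.0)  # overlapping holes


def assert_same_point_set(a, b, tol=1e-9):
    """Order-independent equality of two point clouds."""
    assert a.shape == b.shape
    ka = np.lexsort(np.round(a / tol).astype(np.int64).T)
    kb = np.lexsort(np.round(b / tol).astype(np.int64).T)
    np.testing.assert_allclose(a[ka], b[kb], atol=tol)


class TestMarkers:
    def test_identity_motion_freezes_all_frames(self):
        frames = make_marker_trajectory(RigidTransform.identity(), 5)
        for fr in frames[1:]:
            for lbl, p in frames[0].distal.items():
                np.testing.assert_allclose(fr.distal[lbl], p, atol=1e-12)

    def test_geodesic_frames_carry_proportional_angle(self):
        T = RigidTransform.from_axis_angle((0, 0, 1), 10.0)
        frames = make_marker_trajectory(T, 11)
        for k in (3, 7, 10):
            fit, rms = fit_rigid_transform(frames[0].distal, frames[k].distal)
            assert fit.angle_deg() == pytest.approx(k * 1.0, abs=1e-9)
            assert rms < 1e-9

    def test_noiseless_round_trip_recovers_generator_transform(self):
        T = RigidTransform.from_axis_angle((0.3, 1.0, -0.2), 7.0, (1.2, -0.4, 0.8))
        frames = make_marker_trajectory(T, 11)
        fit, _ = fit_rigid_transform(frames[0].distal, frames[-1].distal)
        np.testing.assert_allclose(fit.rotation, T.rotation, atol=1e-9)
        np.testing.assert_allclose(fit.translation, T.translation, atol=1e-9)

    def test_noiseless_frames_are_exactly_rigid(self):
        T = RigidTransform.from_axis_angle((0.1, 0.9, 0.2), 12.0, (0.5, 0.1, -0.3))
        frames = make_marker_trajectory(T, 8)
        lbls = sorted(frames[0].distal)
        ref = np.array([frames[0].distal[l] for l in lbls])
        d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        for fr in frames:
            pts = np.array([fr.distal[l] for l in lbls])
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.testing.assert_allclose(d, d_ref, atol=1e-9)

    def test_csv_round_trip(self, tmp_path):
        T = RigidTransform.from_axis_angle((0, 1, 0), 3.0, (0.1, 0, 0.2))
        frames = make_marker_trajectory(T, 4, noise_sd=0.05, seed=1)
        path = tmp_path / "markers.csv"
        synthdata.write_markers_csv(frames, path)
        back = synthdata.read_markers_csv(path)
        assert len(back) == 4
        for fr, fb in zip(frames, back):
            for lbl in fr.distal:
                np.testing.assert_allclose(fb.distal[lbl], fr.distal[lbl], atol=1e-9)

    def test_too_few_frames_or_markers_rejected(self):
        with pytest.raises(ValueError):
            make_marker_trajectory(RigidTransform.identity(), 1)
        with pytest.raises(ValueError):
            make_marker_trajectory(
                RigidTransform.identity(), 3,
                proximal_markers={"a": (0, 0, 0), "b": (1, 0, 0)},
            )


class TestDogbone:
    def test_elastic_window_slope_is_exact(self):
        curve = make_dogbone_curve()
        sel = (curve.axial_strain >= 0.0) & (curve.axial_strain <= 0.002)
        slope = np.polyfit(curve.axial_strain[sel], curve.axial_stress[sel], 1)[0]
        assert slope == pytest.approx(synthdata.PEEK_E, rel=1e-12)

    def test_offset_construction_hits_requested_yield(self):
        # analytic bilinear intersection with the 0.2% offset line
        E, H, sy = 1740.5, 50.0, 100.3
        curve = make_dogbone_curve(E=E, hardening_modulus=H, offset_yield=sy)
        eps, sig = curve.axial_strain, curve.axial_stress
        g = sig - E * (eps - 0.002)
        i = np.nonzero((g[:-1] > 0) & (g[1:] <= 0))[0][0]
        w = g[i] / (g[i] - g[i + 1])
        sigma_star = sig[i] + w * (sig[i + 1] - sig[i])
        assert sigma_star == pytest.approx(sy, abs=1e-9)

    def test_lateral_strain_elastic_ratio(self):
        curve = make_dogbone_curve(nu=0.3779)
        sel = curve.axial_strain <= 0.002
        np.testing.assert_allclose(
            curve.lateral_strain[sel], -0.3779 * curve.axial_strain[sel], atol=1e-12
        )

    def test_never_yielding_curve_rejected(self):
        with pytest.raises(ValueError):
            make_dogbone_curve(offset_yield=500.0, max_strain=0.05)

    def test_noise_reproducible_and_zero_at_origin(self):
        a = make_dogbone_curve(noise_sd=0.5, seed=9)
        b = make_dogbone_curve(noise_sd=0.5, seed=9)
        np.testing.assert_array_equal(a.axial_stress, b.axial_stress)
        assert a.axial_stress[0] == 0.0

    def test_csv_round_trip(self, tmp_path):
        curve = make_dogbone_curve(noise_sd=0.2, seed=3)
        p = tmp_path / "curve.csv"
        curve.to_csv(p)
        back = StressStrainCurve.from_csv(p)
        np.testing.assert_allclose(back.axial_stress, curve.axial_stress, rtol=1e-12)
        np.testing.assert_allclose(back.lateral_strain, curve.lateral_strain, rtol=1e-12)
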
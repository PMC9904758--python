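"""Probe-track fitting, magic wand, ROI accumulation, cells, meshes."""

import numpy as np
import pytest
from oracles import bfs_flood_fill

from histoatlas import (
    CellPointSet,
    ProbeGeometry,
    StereotaxicCoord,
    ValidationError,
    accumulate_roi,
    assign_cells,
    compute_plane,
    extract_mesh,
    extract_slice,
    fit_piecewise_affine,
    fit_probe_track,
    magic_wand,
    plan_trajectory,
    plane_covering_volume,
    probe_readout,
    region_overlap,
    trajectory_readout,
    traverse_regions,
)
from histoatlas.planner import count_channels
from histoatlas.reconstruction import (
    ROIVolume,
    mesh_euler_characteristic,
    mesh_surface_area,
    mesh_volume,
)
from histoatlas.registration import AnchorSet


def SC(ap, ml, dv):
    return StereotaxicCoord(ap_mm=ap, ml_mm=ml, dv_mm=dv)


class TestFitProbeTrack:
    def test_collinear_points_zero_rms(self, ellipsoid_atlas):
        atlas, _ = ellipsoid_atlas
        direction = np.array([0.2, 0.1, -1.0])
        direction /= np.linalg.norm(direction)
        pts = np.array([0.0, 0.0, 0.0]) + np.outer(np.linspace(0.1, 1.2, 6), direction)
        fit = fit_probe_track(pts, atlas)
        assert fit.rms_mm == pytest.approx(0.0, abs=1e-12)
        assert abs(fit.direction @ direction) >= 1 - 1e-12

    def test_fewer_than_four_points_rejected(self, ellipsoid_atlas):
        atlas, _ = ellipsoid_atlas
        pts = np.array([[0, 0, 0], [0, 0, -0.5], [0, 0, -1.0]], dtype=float)
        with pytest.raises(ValidationError, match="minimum of 4"):
            fit_probe_track(pts, atlas)

    def test_direction_recovery_under_noise(self, deep_atlas):
        """Median direction error <= 1 degree at 1-voxel isotropic click noise.

        Clicks span a 5-mm insertion, a typical silicon-probe track length.
        """
        atlas, _ = deep_atlas
        sigma_mm = min(atlas.voxel_size_mm)  # 1 voxel
        true_dir = np.array([0.25, -0.15, -1.0])
        true_dir /= np.linalg.norm(true_dir)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            depths = np.linspace(0.0, 5.0, 10)
            pts = np.array([0.1, 0.05, -0.1]) + np.outer(depths, true_dir)
            noisy = pts + rng.normal(0, sigma_mm, pts.shape)
            fit = fit_probe_track(noisy, atlas)
            cosang = np.clip(abs(fit.direction @ true_dir), -1, 1)
            errors.append(np.degrees(np.arccos(cosang)))
        assert np.median(errors) <= 1.0

    def test_direction_error_monotone_in_noise(self, deep_atlas):
        atlas, _ = deep_atlas
        vox = min(atlas.voxel_size_mm)
        true_dir = np.array([0.2, 0.1, -1.0])
        true_dir /= np.linalg.norm(true_dir)
        medians = []
        for sigma in (0.0, 0.5 * vox, 1.0 * vox, 2.0 * vox):
            errs = []
            for seed in range(60):
                rng = np.random.default_rng(1000 + seed)
                pts = np.array([0.1, 0.0, -0.1]) + np.outer(np.linspace(0, 5.0, 10), true_dir)
                noisy = pts + rng.normal(0, sigma, pts.shape)
                fit = fit_probe_track(noisy, atlas)
                errs.append(np.degrees(np.arccos(np.clip(abs(fit.direction @ true_dir), -1, 1))))
            medians.append(np.median(errs))
        assert all(b >= a - 1e-9 for a, b in zip(medians, medians[1:]))

    def test_entry_point_at_box_top_face(self, box_atlas):
        atlas, _ = box_atlas
        # vertical track through the box centred at ml = ap = 0.5 mm; the
        # box's top face is at voxel z = 14.5, i.e. DV = 0.725 mm
        pts = np.array([[0.5, 0.5, dv] for dv in (0.7, 0.55, 0.45, 0.3)])
        fit = fit_probe_track(pts, atlas)
        top_dv = 14.5 * 0.05
        assert fit.entry.dv_mm == pytest.approx(top_dv, abs=0.05 / 2 + 1e-9)
        assert fit.tip.dv_mm < fit.entry.dv_mm

    def test_line_missing_brain_rejected(self, box_atlas):
        atlas, _ = box_atlas
        pts = np.array([[0.9, 0.02, dv] for dv in (0.9, 0.7, 0.5, 0.3)])  # outside box
        with pytest.raises(ValidationError, match="never enters"):
            fit_probe_track(pts, atlas)


class TestProbeReadout:
    def test_plan_reconstruct_consistency(self, slab_atlas):
        """Noiseless clicks along a planned trajectory reproduce the plan read-out."""
        atlas, table = slab_atlas
        traj = plan_trajectory(SC(0.1, 0.05, 0.0), SC(-0.1, 0.25, -1.8), atlas)
        geom = ProbeGeometry(n_channels=96, channel_pitch_um=20.0)
        planned = trajectory_readout(
            traj, traverse_regions(traj, atlas), count_channels(traj, geom, atlas), table
        )
        clicks = traj.point_at_depth(np.linspace(0.6, traj.insertion_length_mm, 8))
        fit = fit_probe_track(clicks, atlas)
        recon = probe_readout(fit, geom, atlas, table)
        assert [r["label_id"] for r in recon.regions] == [r["label_id"] for r in planned.regions]
        assert [r["n_channels"] for r in recon.regions] == [r["n_channels"] for r in planned.regions]
        for a, b in zip(recon.regions, planned.regions):
            assert a["path_length_mm"] == pytest.approx(b["path_length_mm"], abs=2 * min(atlas.voxel_size_mm))
        assert recon.lateral_tilt_deg == pytest.approx(planned.lateral_tilt_deg, abs=1e-6)

    def test_vertical_track_matches_slab_order(self, slab_atlas):
        atlas, table = slab_atlas
        pts = np.array([[0.0, 0.0, dv] for dv in (-0.5, -0.8, -1.1, -1.5, -1.9)])
        fit = fit_probe_track(pts, atlas)
        report = probe_readout(fit, None, atlas, table)
        assert [r["label_id"] for r in report.regions] == [3, 2, 1]

    def test_report_serializes_round_trip(self, slab_atlas):
        import json

        from histoatlas.planner import PlanReport

        atlas, table = slab_atlas
        pts = np.array([[0.0, 0.0, dv] for dv in (-0.5, -0.9, -1.3, -1.7)])
        report = probe_readout(fit_probe_track(pts, atlas), None, atlas, table)
        assert PlanReport.from_dict(json.loads(json.dumps(report.to_dict()))).to_dict() == report.to_dict()


class TestMagicWand:
    def test_uniform_image_saturates(self):
        img = np.full((12, 17), 42.0)
        assert magic_wand(img, (3, 4), 0.0).all()

    def test_two_plateaus_selects_seed_plateau_exactly(self):
        img = np.full((30, 30), 100.0)
        img[8:20, 5:25] = 200.0
        mask = magic_wand(img, (2, 2), 50.0)  # seed in the 100-plateau
        np.testing.assert_array_equal(mask, img == 100.0)
        np.testing.assert_array_equal(mask, bfs_flood_fill(img, (2, 2), 50.0, 4))

    def test_isolated_seed_single_pixel(self):
        img = np.zeros((5, 5))
        img[2, 2] = 99.0
        mask = magic_wand(img, (2, 2), 0.0)
        assert mask.sum() == 1 and mask[2, 2]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_bfs_oracle_on_random_plateaus(self, connectivity, rng):
        for _ in range(50):
            img = (rng.integers(0, 5, (24, 24)) * 60).astype(float)
            x, y = int(rng.integers(0, 24)), int(rng.integers(0, 24))
            tol = float(rng.choice([0.0, 60.0, 130.0]))
            ours = magic_wand(img, (x, y), tol, connectivity=connectivity)
            np.testing.assert_array_equal(ours, bfs_flood_fill(img, (x, y), tol, connectivity))

    def test_rgb_converted_to_luminance(self):
        img = np.zeros((6, 6, 3), dtype=np.uint8)
        img[:3] = (255, 0, 0)
        mask = magic_wand(img, (0, 0), 10.0)
        assert mask[:3].all() and not mask[3:].any()

    def test_seed_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError, match="seed"):
            magic_wand(np.zeros((5, 5)), (9, 0), 1.0)


def _coronal_slice_masks(atlas, label, j_range, step=1):
    masks = []
    for j in j_range[::step]:
        pos = (j - atlas.bregma_voxel[1]) * atlas.voxel_size_mm[1]
        plane = compute_plane("coronal", pos, pixel_size_mm=atlas.voxel_size_mm[0], atlas=atlas)
        plane, shape = plane_covering_volume(atlas, plane)
        sl = extract_slice(atlas, plane, shape)
        selected = sl.label_image > 0 if label is None else sl.label_image == label
        masks.append((selected, plane))
    return masks


class TestAccumulateROI:
    def test_one_slice_identity_projection_counts_pixels(self, box_atlas):
        atlas, _ = box_atlas
        masks = _coronal_slice_masks(atlas, 1, [8])
        assert int(masks[0][0].sum()) == 100
        roi = accumulate_roi(masks, atlas)
        assert roi.count == 100
        assert roi.volume_mm3 == pytest.approx(100 * 0.05**3, abs=1e-12)

    def test_overlapping_slices_no_double_counting(self, box_atlas):
        atlas, _ = box_atlas
        masks = _coronal_slice_masks(atlas, 1, [8, 8, 8])
        roi = accumulate_roi(masks, atlas)
        assert roi.count == 100  # set union, not 300

    def test_union_matches_brute_force_voxel_set(self, ellipsoid_atlas):
        atlas, _ = ellipsoid_atlas
        masks = _coronal_slice_masks(atlas, 2, range(10, 30))
        roi = accumulate_roi(masks, atlas)
        expected = {tuple(v) for v in np.argwhere(atlas.annotation == 2)}
        assert {tuple(v) for v in roi.voxels} == expected

    def test_slab_accumulation_recovers_ellipsoid_volume(self, ellipsoid_atlas):
        """Every 4th slice with matching slab thickness: volume within 10%."""
        atlas, _ = ellipsoid_atlas
        spacing_vox = 4
        masks = _coronal_slice_masks(atlas, None, range(2, 38), step=spacing_vox)
        slab = spacing_vox * atlas.voxel_size_mm[1]
        roi = accumulate_roi(masks, atlas, slab_thickness_mm=slab)
        analytic_mm3 = 4 / 3 * np.pi * 17 * 17 * 15 * 0.05**3
        assert abs(roi.volume_mm3 - analytic_mm3) / analytic_mm3 < 0.10

    def test_registered_mask_routes_through_warp(self, box_atlas):
        atlas, _ = box_atlas
        # identity registration on a 100-px histology mask of the box slice
        masks = _coronal_slice_masks(atlas, 1, [8])
        slice_mask, plane = masks[0]
        corners = np.array([[0, 0], [19, 0], [0, 19], [19, 19]], dtype=float)
        ident = fit_piecewise_affine(AnchorSet(src=corners, dst=corners))
        # the slice rendered as an image has rows = s, cols = t; under the
        # identity warp the registered path must reproduce the direct one
        roi = accumulate_roi([(slice_mask, plane, ident)], atlas)
        assert roi.count == 100

    def test_empty_masks_give_empty_roi(self, box_atlas):
        atlas, _ = box_atlas
        roi = accumulate_roi([(np.zeros((10, 10), dtype=bool),
                               compute_plane("coronal", 0.0, atlas=atlas))], atlas)
        assert roi.count == 0 and roi.volume_mm3 == 0.0


class TestRegionOverlap:
    def test_full_coverage_is_100_percent(self, box_atlas):
        atlas, table = box_atlas
        vox = np.argwhere(atlas.annotation == 1)
        roi = ROIVolume(voxels=vox, voxel_size_mm=atlas.voxel_size_mm)
        rows = region_overlap(roi, atlas, table)
        assert len(rows) == 1
        assert rows[0]["percent_of_region"] == pytest.approx(100.0)
        assert rows[0]["percent_of_roi"] == pytest.approx(100.0)

    def test_half_box_is_50_percent(self, box_atlas):
        atlas, table = box_atlas
        vox = np.argwhere(atlas.annotation == 1)
        half = vox[vox[:, 2] < 10]  # bottom half of the [5, 15) box
        rows = region_overlap(ROIVolume(half, atlas.voxel_size_mm), atlas, table)
        assert rows[0]["percent_of_region"] == pytest.approx(50.0, abs=100 / 10)  # one voxel layer

    def test_empty_roi_empty_readout(self, box_atlas):
        atlas, table = box_atlas
        roi = ROIVolume(np.empty((0, 3), dtype=np.int64), atlas.voxel_size_mm)
        assert region_overlap(roi, atlas, table) == []

    def test_ordered_by_overlap_descending_background_last(self, ellipsoid_atlas):
        atlas, table = ellipsoid_atlas
        vox = np.argwhere(atlas.annotation >= 0)[::17][:3000]  # mixed labels incl. 0
        rows = region_overlap(ROIVolume(np.unique(vox, axis=0), atlas.voxel_size_mm), atlas, table)
        non_bg = [r for r in rows if r["label_id"] != 0]
        overlaps = [r["overlap_voxels"] for r in non_bg]
        assert overlaps == sorted(overlaps, reverse=True)
        assert rows[-1]["label_id"] == 0

    def test_percentage_monotone_as_slices_added(self, ellipsoid_atlas):
        atlas, table = ellipsoid_atlas
        percents = []
        for upto in (15, 20, 25, 30):
            masks = _coronal_slice_masks(atlas, 2, range(10, upto))
            roi = accumulate_roi(masks, atlas)
            rows = [r for r in region_overlap(roi, atlas, table) if r["label_id"] == 2]
            percents.append(rows[0]["percent_of_region"] if rows else 0.0)
        assert all(b >= a for a, b in zip(percents, percents[1:]))
        assert all(0 <= p <= 100 for p in percents)


class TestAssignCells:
    def test_points_inside_one_region(self, box_atlas):
        atlas, table = box_atlas
        pts = np.full((10, 3), 0.5)  # centre of the box, (ML, AP, DV) mm
        out = assign_cells(CellPointSet(pts), atlas, table)
        assert out["per_region"][1]["count"] == 10
        assert out["total"] == 10

    def test_straddling_points_match_per_point_oracle(self, slab_atlas, rng):
        from histoatlas.atlas_core import sample_labels, stereotaxic_to_voxel

        atlas, table = slab_atlas
        pts = rng.uniform(-1.2, 1.2, (200, 3)) * np.array([1, 1, 1.5]) - [0, 0, 0.5]
        out = assign_cells(CellPointSet(pts), atlas, table)
        vox, _ = stereotaxic_to_voxel(pts, atlas)
        labels = sample_labels(atlas, vox)
        for lab in np.unique(labels):
            assert out["per_region"][int(lab)]["count"] == int((labels == lab).sum())

    def test_group_marginals_consistent(self, box_atlas):
        atlas, table = box_atlas
        pts = np.full((6, 3), 0.5)
        groups = ["inj1", "inj1", "inj2", "inj2", "inj2", "inj1"]
        out = assign_cells(CellPointSet(pts, groups=groups), atlas, table)
        assert out["per_region_group"]["1|inj1"] == 3
        assert out["per_region_group"]["1|inj2"] == 3
        assert out["per_region"][1]["count"] == 6


class TestMesh:
    def test_sphere_volume_within_5_percent(self):
        r = 8
        g = np.arange(24) + 0.5
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        sphere = ((X - 12) ** 2 + (Y - 12) ** 2 + (Z - 12) ** 2) <= r**2
        verts, faces = extract_mesh(sphere, (1.0, 1.0, 1.0))
        vol = mesh_volume(verts, faces)
        analytic = 4 / 3 * np.pi * r**3
        assert abs(vol - analytic) / analytic < 0.05

    def test_box_surface_area_within_10_percent(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[4:16, 4:16, 4:16] = True  # 12^3 cube
        verts, faces = extract_mesh(mask, (1.0, 1.0, 1.0))
        area = mesh_surface_area(verts, faces)
        assert abs(area - 6 * 12**2) / (6 * 12**2) < 0.10

    def test_single_voxel_closed_genus_zero(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        verts, faces = extract_mesh(mask, (1.0, 1.0, 1.0))
        assert mesh_euler_characteristic(verts, faces) == 2

    def test_cross_check_against_trimesh(self):
        import trimesh

        g = np.arange(20) + 0.5
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        blob = ((X - 10) ** 2 / 36 + (Y - 10) ** 2 / 25 + (Z - 10) ** 2 / 16) <= 1
        verts, faces = extract_mesh(blob, (0.5, 0.5, 0.5))
        tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        assert mesh_volume(verts, faces) == pytest.approx(abs(tm.volume), rel=1e-9)
        assert mesh_surface_area(verts, faces) == pytest.approx(tm.area, rel=1e-9)
        assert mesh_euler_characteristic(verts, faces) == tm.euler_number

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            extract_mesh(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))
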
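"""Cylinder masks, native-grid statistics, paired measurement transfer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decbct.errors import EmptyROIError
from decbct.geometry import Grid, RigidTransform, VoxelVolume
from decbct.roi import (
    CylinderROI,
    cylinder_mask,
    paired_roi_means,
    read_rois_csv,
    roi_statistics,
    transform_cylinder,
    write_rois_csv,
)


def volume_with(values, spacing=(1.0, 1.0, 1.0), centered=True):
    dims = values.shape
    grid = Grid.centered(dims, spacing) if centered else Grid(dims, spacing)
    return VoxelVolume(values, grid)


class TestCylinderMask:
    def test_center_voxel_included_axial_overshoot_excluded(self):
        vol = volume_with(np.zeros((21, 21, 21)), spacing=(0.5, 0.5, 0.5))
        roi = CylinderROI("c", (0, 0, 0), height=4.0, diameter=1.0)
        idx = cylinder_mask(vol, roi)
        assert [10, 10, 10] in idx.tolist()  # voxel at the ROI center
        zs = idx[:, 2]
        # voxel centers beyond height/2 + one spacing step are excluded
        assert zs.max() <= 10 + int(np.ceil(2.0 / 0.5))

    def test_mask_volume_matches_analytic_cylinder(self):
        # 0.05 mm grid: |mask| * voxel volume ~ pi r^2 h within 2%
        vol = volume_with(np.zeros((40, 40, 100)), spacing=(0.05, 0.05, 0.05))
        roi = CylinderROI("c", (0, 0, 0), height=4.5, diameter=1.2)
        idx = cylinder_mask(vol, roi)
        measured = len(idx) * 0.05**3
        analytic = np.pi * 0.6**2 * 4.5
        assert abs(measured - analytic) / analytic < 0.02

    def test_no_intersection_raises(self):
        vol = volume_with(np.zeros((10, 10, 10)))
        with pytest.raises(EmptyROIError):
            cylinder_mask(vol, CylinderROI("far", (100, 100, 100), 4.5, 1.2))

    def test_membership_invariant_under_joint_rigid_motion(self):
        # transforming both the ROI and the grid by the same rigid map keeps
        # the same voxel index set
        vol = volume_with(np.zeros((30, 30, 30)), spacing=(0.4, 0.4, 0.4))
        roi = CylinderROI("c", (0.13, -0.2, 0.4), 4.5, 1.2, angles=(10, -20, 30))
        t = RigidTransform.from_euler((14, 5, -40), translation=(3.1, -0.8, 2.2))
        g = vol.grid
        moved_grid = Grid(
            dims=g.dims,
            spacing=g.spacing,
            origin=tuple(t.apply(np.asarray(g.origin))),
            direction=t.rotation @ g.direction,
        )
        moved_vol = VoxelVolume(vol.values, moved_grid)
        moved_roi = transform_cylinder(roi, t)
        idx_a = cylinder_mask(vol, roi)
        idx_b = cylinder_mask(moved_vol, moved_roi)
        assert np.array_equal(
            idx_a[np.lexsort(idx_a.T)], idx_b[np.lexsort(idx_b.T)]
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        dh=st.floats(0.0, 2.0),
        dd=st.floats(0.0, 0.8),
    )
    def test_shrinking_never_adds_voxels(self, dh, dd):
        vol = volume_with(np.zeros((25, 25, 25)), spacing=(0.3, 0.3, 0.3))
        big = CylinderROI("b", (0.1, 0.05, -0.1), 5.0, 1.4, angles=(5, 10, -15))
        small = CylinderROI(
            "s", big.center, big.height - dh, big.diameter - dd,
            angles=big.angles, validate=False,
        )
        big_set = {tuple(r) for r in cylinder_mask(vol, big)}
        try:
            small_set = {tuple(r) for r in cylinder_mask(vol, small)}
        except EmptyROIError:
            small_set = set()
        assert small_set <= big_set


class TestROIStatistics:
    def test_constant_volume(self):
        vol = volume_with(np.full((21, 21, 21), 700.0), spacing=(0.5, 0.5, 0.5))
        s = roi_statistics(vol, CylinderROI("c", (0, 0, 0), 4.5, 1.2))
        assert (s.mean, s.sd, s.min, s.max) == (700.0, 0.0, 700.0, 700.0)

    def test_two_voxel_closed_form(self):
        values = np.full((5, 5, 9), 1e9)
        grid = Grid((5, 5, 9), (10.0, 10.0, 1.0))
        values[0, 0, 4] = 600.0
        values[0, 0, 5] = 800.0
        vol = VoxelVolume(values, grid)
        roi = CylinderROI("two", (0.0, 0.0, 4.5), height=1.2, diameter=0.5, validate=False)
        s = roi_statistics(vol, roi)
        assert s.n_voxels == 2
        assert s.mean == 700.0
        assert s.sd == pytest.approx(141.4214, abs=1e-3)

    def test_single_voxel_sd_zero_with_flag(self):
        vol = volume_with(np.zeros((9, 9, 9)), spacing=(2.0, 2.0, 2.0))
        roi = CylinderROI("one", (0, 0, 0), height=1.0, diameter=1.0, validate=False)
        with pytest.warns(UserWarning, match="single voxel"):
            s = roi_statistics(vol, roi)
        assert s.n_voxels == 1 and s.sd == 0.0 and s.single_voxel

    def test_noiseless_cortical_roi_mean_exact(self, jaw_scene, jaw_study_reduced):
        from decbct.calibration import CalibrationModel
        cortical_low = jaw_scene.materials["cortical"].ct_number("low")
        anchor = jaw_scene.anchors[0]
        s = roi_statistics(
            jaw_study_reduced.vol_low, CylinderROI("c", anchor.point, 4.5, 1.2)
        )
        assert s.mean == pytest.approx(cortical_low, abs=1e-9)

    def test_out_of_range_geometry_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            CylinderROI("odd", (0, 0, 0), height=9.0, diameter=1.2)


class TestTransformCylinder:
    def test_identity_and_pure_translation(self):
        roi = CylinderROI("r", (1.0, 2.0, 3.0), 4.5, 1.2, angles=(10, 20, 30))
        same = transform_cylinder(roi, RigidTransform.identity())
        assert np.allclose(same.center, roi.center)
        assert np.allclose(same.angles, roi.angles, atol=1e-12)
        moved = transform_cylinder(roi, RigidTransform(translation=(-3, 0, 0)))
        assert np.allclose(moved.center, (-2.0, 2.0, 3.0))
        assert np.allclose(moved.angles, roi.angles, atol=1e-12)
        assert (moved.height, moved.diameter) == (roi.height, roi.diameter)

    def test_point_set_equality_monte_carlo(self):
        # {p inside roi'} must equal {T(q) : q inside roi}
        rng = np.random.default_rng(21)
        roi = CylinderROI("r", (2.0, -1.0, 0.5), 4.5, 1.2, angles=(25, -40, 60))
        t = RigidTransform.from_euler((33, 12, -75), translation=(5, -3, 2))
        moved = transform_cylinder(roi, t)
        q = np.asarray(roi.center) + rng.uniform(-4, 4, size=(10_000, 3))
        inside_before = roi.contains(q)
        inside_after = moved.contains(t.apply(q))
        assert np.array_equal(inside_before, inside_after)


class TestPairedROIMeans:
    def test_identity_transform_identical_volumes(self, jaw_scene, jaw_study_reduced):
        vol = jaw_study_reduced.vol_low
        rois = [
            CylinderROI(a.label, a.point, 4.5, 1.2, group=a.group)
            for a in jaw_scene.anchors
        ]
        res = paired_roi_means(vol, vol, rois, RigidTransform.identity())
        assert len(res.pairs) == 15
        assert sum(p.group == "mandible" for p in res.pairs) == 9
        assert sum(p.group == "maxilla" for p in res.pairs) == 6
        for p in res.pairs:
            assert p.mean_mdct == pytest.approx(p.mean_decbct, abs=1e-12)

    def test_known_misalignment_pairs_agree(self, jaw_scene, jaw_study_reduced):
        study = jaw_study_reduced
        rois = [
            CylinderROI(a.label, a.point, 4.5, 1.2, group=a.group)
            for a in jaw_scene.anchors
        ]
        res = paired_roi_means(
            study.vol_low, study.vol_mdct, rois, study.true_transform.inverse()
        )
        assert len(res.pairs) == 15 and not res.excluded
        low_ct = jaw_scene.materials["cortical"].ct_number("low")
        mdct_ct = jaw_scene.materials["cortical"].ct_number("mdct") * 0.95
        for p in res.pairs:
            assert abs(p.mean_decbct - low_ct) < 2.0
            assert abs(p.mean_mdct - mdct_ct) < 2.0

    def test_out_of_field_roi_reported_excluded(self, jaw_study_reduced):
        rois = [CylinderROI("gone", (500.0, 0.0, 0.0), 4.5, 1.2, group="mandible")]
        res = paired_roi_means(
            jaw_study_reduced.vol_low,
            jaw_study_reduced.vol_mdct,
            rois,
            RigidTransform.identity(),
        )
        assert not res.pairs
        assert res.excluded and res.excluded[0][0] == "gone"


def test_roi_csv_round_trip(tmp_path):
    rois = [
        CylinderROI("mandible_1", (1.0, 2.0, 3.0), 4.5, 1.2, (10, -5, 30), group="mandible"),
        CylinderROI("maxilla_1", (-1.0, 0.5, 2.0), 5.0, 1.4, (0, 0, 0), group="maxilla"),
    ]
    path = tmp_path / "rois.csv"
    write_rois_csv(rois, path)
    loaded = read_rois_csv(path)
    for a, b in zip(rois, loaded):
        assert a.label == b.label and a.group == b.group
        assert np.allclose(a.center, b.center) and np.allclose(a.angles, b.angles)
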
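"""Density-line calibration: fits, projection, HU mapping, recovery.

Fit results are checked against independent brute-force oracles: a dense
grid search over line angle for the total-least-squares fit, a fine grid
minimization for the orthogonal projection, and the normal-equations
closed form for the HU map.
"""

import numpy as np
import pytest

from decbct.calibration import (
    CalibrationModel,
    DensityLine,
    RegionSample,
    apply_calibration,
    extract_region_samples,
    fit_density_line,
    fit_hu_map,
    project_to_density,
)
from decbct.errors import DegenerateFitError, GeometryError
from decbct.geometry import Grid, VoxelVolume
from decbct.pipeline import calibrate_synthetic_phantom, known_hu_table
from decbct.phantom import NoiseConfig


def orthogonal_sse(points: np.ndarray, angle: float) -> float:
    """Sum of squared orthogonal residuals to the best line at direction angle."""
    u = np.array([np.cos(angle), np.sin(angle)])
    centered = points - points.mean(axis=0)
    t = centered @ u
    resid = centered - np.outer(t, u)
    return float((resid**2).sum())


def sample(label, low, high, hu=None):
    return RegionSample(label=label, mean_low=low, mean_high=high, known_hu=hu)


class TestExtractRegionSamples:
    def test_constant_volumes(self):
        g = Grid((6, 6, 6), (1, 1, 1))
        low = VoxelVolume(np.full(g.dims, 100.0), g)
        high = VoxelVolume(np.full(g.dims, 80.0), g)
        mask = np.zeros(g.dims, dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        (s,) = extract_region_samples(low, high, {"blob": mask})
        assert (s.mean_low, s.mean_high) == (100.0, 80.0)

    def test_mismatched_grids_rejected(self):
        low = VoxelVolume(np.zeros((6, 6, 6)), Grid((6, 6, 6), (1, 1, 1)))
        high = VoxelVolume(np.zeros((6, 6, 6)), Grid((6, 6, 6), (1, 1, 2)))
        with pytest.raises(GeometryError):
            extract_region_samples(low, high, {})

    def test_empty_and_tiny_masks_rejected_by_name(self):
        g = Grid((6, 6, 6), (1, 1, 1))
        vol = VoxelVolume(np.zeros(g.dims), g)
        with pytest.raises(DegenerateFitError, match="empty_region"):
            extract_region_samples(vol, vol, {"empty_region": np.zeros(g.dims, bool)})
        tiny = np.zeros(g.dims, bool)
        tiny[0, 0, 0] = True
        with pytest.raises(DegenerateFitError, match="tiny"):
            extract_region_samples(vol, vol, {"tiny": tiny})

    def test_noiseless_phantom_samples_are_analytic(self, cal_scene, cal_noiseless):
        vol_low, vol_high, masks = cal_noiseless
        for s in extract_region_samples(vol_low, vol_high, masks):
            m = cal_scene.materials[s.label]
            assert s.mean_low == pytest.approx(m.ct_number("low"), abs=1e-9)
            assert s.mean_high == pytest.approx(m.ct_number("high"), abs=1e-9)


class TestFitDensityLine:
    def test_two_points_and_collinear(self):
        line = fit_density_line([sample("a", 0, 0), sample("b", 1, 2), sample("c", 2, 4)])
        assert np.allclose(np.abs(line.u), np.array([1, 2]) / np.sqrt(5))
        t = [project_to_density(p, line) for p in [(0, 0), (1, 2), (2, 4)]]
        # zero orthogonal residual: projections land back on the points
        for ti, p in zip(t, [(0, 0), (1, 2), (2, 4)]):
            back = np.asarray(line.p0) + ti * np.asarray(line.u)
            assert np.allclose(back, p, atol=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_density_line([sample("a", 5, 5), sample("b", 5, 5)])

    def test_tls_beats_dense_angle_grid_search(self):
        rng = np.random.default_rng(12)
        pts = np.column_stack([rng.uniform(-500, 1500, 6), rng.uniform(-500, 1500, 6)])
        samples = [sample(f"s{i}", *p) for i, p in enumerate(pts)]
        line = fit_density_line(samples)
        tls_angle = np.arctan2(line.u[1], line.u[0])
        tls_sse = orthogonal_sse(pts, tls_angle)
        grid_sse = min(orthogonal_sse(pts, a) for a in np.linspace(0, np.pi, 200001))
        assert tls_sse <= grid_sse + 1e-9

    def test_fit_is_order_invariant(self):
        pts = [sample("a", 0, 10), sample("b", 100, 95), sample("c", 400, 330)]
        l1 = fit_density_line(pts)
        l2 = fit_density_line(pts[::-1])
        assert np.allclose(l1.p0, l2.p0) and np.allclose(l1.u, l2.u)


class TestProjection:
    def test_on_line_cases(self):
        line = DensityLine(p0=(10.0, 20.0), u=(0.6, 0.8))
        assert project_to_density((10.0, 20.0), line) == 0.0
        p = np.array([10.0, 20.0]) + 3.0 * np.array([0.6, 0.8])
        assert project_to_density(tuple(p), line) == pytest.approx(3.0, abs=1e-12)

    def test_projection_minimizes_distance(self):
        rng = np.random.default_rng(2)
        line = fit_density_line([sample("a", 0, 0), sample("b", 3, 1)])
        for _ in range(5):
            pair = rng.uniform(-100, 100, 2)
            t_star = project_to_density(pair, line)
            ts = np.linspace(t_star - 50, t_star + 50, 100001)
            pts_on_line = np.asarray(line.p0) + ts[:, None] * np.asarray(line.u)
            d = np.linalg.norm(pts_on_line - pair, axis=1)
            assert abs(ts[np.argmin(d)] - t_star) < 1e-3


class TestFitHUMap:
    def test_two_point_interpolation(self):
        line = DensityLine(p0=(0.0, 0.0), u=(1.0, 0.0))
        samples = [sample("air", -800, 0, hu=-1000.0), sample("ha", 1200, 0, hu=1000.0)]
        hu_map = fit_hu_map(samples, line)
        assert hu_map.slope == pytest.approx(2000.0 / 2000.0)
        assert hu_map.slope * -800 + hu_map.intercept == pytest.approx(-1000.0)
        assert hu_map.slope * 1200 + hu_map.intercept == pytest.approx(1000.0)

    def test_matches_normal_equations_closed_form(self):
        rng = np.random.default_rng(9)
        line = DensityLine(p0=(50.0, 40.0), u=(np.cos(0.7), np.sin(0.7)))
        samples = [
            sample(f"s{i}", *rng.uniform(-1000, 1500, 2), hu=float(rng.uniform(-1000, 1500)))
            for i in range(5)
        ]
        hu_map = fit_hu_map(samples, line)
        t = np.array([project_to_density(s.point, line) for s in samples])
        hu = np.array([s.known_hu for s in samples])
        a = np.column_stack([t, np.ones_like(t)])
        slope, intercept = np.linalg.solve(a.T @ a, a.T @ hu)
        assert hu_map.slope == pytest.approx(slope, abs=1e-9)
        assert hu_map.intercept == pytest.approx(intercept, abs=1e-9)

    def test_too_few_known_hu_rejected(self):
        line = DensityLine(p0=(0.0, 0.0), u=(1.0, 0.0))
        with pytest.raises(DegenerateFitError):
            fit_hu_map([sample("a", 0, 0, hu=-1000.0), sample("b", 5, 5)], line)


class TestApplyCalibration:
    def test_constant_at_p0_maps_to_intercept(self):
        g = Grid((4, 4, 4), (1, 1, 1))
        line = DensityLine(p0=(100.0, 80.0), u=(0.8, 0.6))
        from decbct.calibration import HUMap

        low = VoxelVolume(np.full(g.dims, 100.0), g)
        high = VoxelVolume(np.full(g.dims, 80.0), g)
        out = apply_calibration(low, high, line, HUMap(slope=2.0, intercept=0.0))
        assert np.allclose(out.values, 0.0)
        assert out.value_kind == "hu"

    def test_noiseless_phantom_recovers_known_hu_exactly(self, cal_scene, cal_noiseless):
        vol_low, vol_high, masks = cal_noiseless
        samples = extract_region_samples(vol_low, vol_high, masks, known_hu_table(cal_scene))
        model = CalibrationModel.fit(samples)
        hu = model.apply(vol_low, vol_high)
        for name, mask in masks.items():
            true_hu = cal_scene.materials[name].ct_number("mdct")
            assert np.abs(hu.values[mask] - true_hu).max() < 1e-6, name

    def test_noisy_phantom_recovers_insert_means_within_3hu(self, small_grid):
        model, scene, vol_low, vol_high, masks = calibrate_synthetic_phantom(
            seed=123, noise=NoiseConfig(cbct_sd=30.0, mdct_sd=0.0), grid=small_grid
        )
        hu = model.apply(vol_low, vol_high)
        for name in ("ha200", "ha400", "ha800", "ha1200", "air"):
            true_hu = scene.materials[name].known_hu
            assert abs(float(hu.values[masks[name]].mean()) - true_hu) < 3.0, name

    def test_recalibration_self_consistent_under_channelwise_affine_maps(
        self, cal_scene, cal_noiseless
    ):
        # remapping both channels by one monotone affine map keeps pairs on a
        # line and preserves orthogonal projections up to scale; refitting on
        # the remapped phantom must reproduce identical HU output everywhere
        vol_low, vol_high, masks = cal_noiseless
        table = known_hu_table(cal_scene)
        base = CalibrationModel.fit(extract_region_samples(vol_low, vol_high, masks, table))
        hu0 = base.apply(vol_low, vol_high)

        low2 = VoxelVolume(1.2 * vol_low.values + 30.0, vol_low.grid)
        high2 = VoxelVolume(1.2 * vol_high.values + 30.0, vol_high.grid)
        model2 = CalibrationModel.fit(extract_region_samples(low2, high2, masks, table))
        hu2 = model2.apply(low2, high2)
        assert np.abs(hu2.values - hu0.values).max() < 1e-6

    def test_model_json_round_trip(self, tmp_path, cal_scene, cal_noiseless):
        vol_low, vol_high, masks = cal_noiseless
        samples = extract_region_samples(vol_low, vol_high, masks, known_hu_table(cal_scene))
        model = CalibrationModel.fit(samples)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = CalibrationModel.from_json(path)
        assert loaded.hu_map.slope == pytest.approx(model.hu_map.slope, abs=1e-12)
        assert np.allclose(loaded.line.p0, model.line.p0)
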
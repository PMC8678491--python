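"""Cup-depth sampling, metric correction, calibration, depth profiles."""

import numpy as np
import pytest

from lffundus.depth_map import DepthMap
from lffundus.image_quality import papilla_center
from lffundus.papilla_metrics import (
    NoSampleError,
    depth_profile,
    fit_linear_calibration,
    model_papilla_depth,
    papilla_depth,
    sample_mean_depth,
)
from lffundus.plenoptic_model import MagnificationModel
from lffundus.synthetic_data import ParameterError

MAG = MagnificationModel(lateral_mag=1.5)


def _map(values, valid=None):
    values = np.asarray(values, dtype=float)
    valid = np.ones_like(values, bool) if valid is None else np.asarray(valid, bool)
    return DepthMap(values, valid)


class TestSampleMeanDepth:
    def test_constant_map(self):
        s = sample_mean_depth(_map(np.full((40, 40), 3.0)), (20, 20), 20)
        assert s.mean_v == pytest.approx(3.0)
        assert s.n_valid <= s.area_px + 8  # discretized circle

    def test_area_one_is_single_pixel(self):
        vals = np.zeros((10, 10))
        vals[4, 6] = 7.0
        s = sample_mean_depth(_map(vals), (6, 4), 1)
        assert s.mean_v == 7.0
        assert s.n_valid == 1

    def test_half_and_half_equals_loop_oracle(self):
        vals = np.where(np.arange(30)[None, :] < 15, 2.0, 4.0) * np.ones((30, 1))
        dmap = _map(vals)
        s = sample_mean_depth(dmap, (14.5, 15), 40)
        r = np.sqrt(40 / np.pi)
        acc = [
            vals[y, x]
            for y in range(30)
            for x in range(30)
            if (x - 14.5) ** 2 + (y - 15) ** 2 <= r**2
        ]
        assert 2.0 <= s.mean_v <= 4.0
        assert s.mean_v == pytest.approx(np.mean(acc))
        assert s.n_valid == len(acc)

    def test_no_valid_pixels_raises(self):
        dmap = _map(np.zeros((20, 20)), np.zeros((20, 20), bool))
        with pytest.raises(NoSampleError):
            sample_mean_depth(dmap, (10, 10), 20)


class TestPapillaDepth:
    def test_base_vs_rim_difference_with_axial_correction(self):
        vals = np.full((50, 50), 1.0)
        vals[20:30, 20:30] = 3.0  # deep ground region
        dmap = _map(vals)
        res = papilla_depth(dmap, (25, 25), (40, 25), (25, 40), 20, MAG)
        assert res.depth_h_vmm == pytest.approx(2.0, abs=0.05)
        assert res.depth_mean_vmm == pytest.approx(2.0, abs=0.05)
        assert res.depth_mm == pytest.approx(2.0 / 2.25, abs=0.03)

    def test_h_and_v_averaging_rule(self):
        vals = np.full((60, 60), 3.0)
        vals[:, 50:] = 1.0  # horizontal rim shallower
        vals[50:, :] = 0.8  # vertical rim shallower still
        dmap = _map(vals)
        res = papilla_depth(dmap, (20, 20), (55, 20), (20, 55), 10, MAG)
        assert res.depth_mean_vmm == pytest.approx(
            (res.depth_h_vmm + res.depth_v_vmm) / 2
        )

    def test_swapping_rim_samples_is_symmetric(self):
        rng = np.random.default_rng(2)
        dmap = _map(3.0 + 0.1 * rng.standard_normal((60, 60)))
        a = papilla_depth(dmap, (30, 30), (50, 30), (30, 50), 20, MAG)
        b = papilla_depth(dmap, (30, 30), (30, 50), (50, 30), 20, MAG)
        assert a.depth_mean_vmm == pytest.approx(b.depth_mean_vmm)
        assert a.depth_mm == pytest.approx(b.depth_mm)

    def test_metric_depth_always_smaller_than_virtual(self):
        vals = np.full((50, 50), 1.0)
        vals[20:30, 20:30] = 4.0
        res = papilla_depth(_map(vals), (25, 25), (40, 25), (25, 40), 20, MAG)
        assert res.depth_mm < res.depth_mean_vmm

    def test_failed_sample_propagates(self):
        valid = np.ones((50, 50), bool)
        valid[:, 35:] = False
        dmap = _map(np.where(valid, 2.0, 0.0), valid)
        with pytest.raises(NoSampleError):
            papilla_depth(dmap, (25, 25), (45, 25), (25, 45), 10, MAG)


class TestModelPapillaDepth:
    def _geom(self, cx, cy, r):
        return papilla_center(
            {"N": (cx, cy - r), "E": (cx + r, cy), "S": (cx, cy + r), "W": (cx - r, cy)}
        )

    def test_flat_scene_measures_zero(self):
        dmap = _map(np.full((120, 120), 3.2))
        res = model_papilla_depth(dmap, self._geom(60, 60, 20), MAG)
        assert res.depth_mm == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_cup_recovered_within_tolerance(
        self, cup_dmap_desk, cup_scene_desk, desk_cam
    ):
        from lffundus.pipeline import scene_papilla_geometry

        geom = scene_papilla_geometry(cup_scene_desk, desk_cam, cup_dmap_desk.resolution)
        res = model_papilla_depth(cup_dmap_desk, geom, desk_cam.magnification)
        assert res.depth_mm == pytest.approx(0.8, abs=0.05)


class TestLinearCalibration:
    def test_exact_line(self):
        pairs = [(x, 2 * x + 1) for x in (0.2, 0.4, 0.8, 1.0)]
        fit = fit_linear_calibration(pairs)
        assert fit.slope == pytest.approx(2.0)
        assert fit.offset == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_two_points_perfect_fit(self):
        fit = fit_linear_calibration([(0.0, 1.0), (1.0, 3.0)])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_identical_truth_values_rejected(self):
        with pytest.raises(ParameterError):
            fit_linear_calibration([(0.5, 1.0), (0.5, 2.0)])

    def test_noisy_line_slope_within_sampling_error(self):
        rng = np.random.default_rng(42)
        n, sd, slope = 40, 0.05, 1.3
        x = np.linspace(0.1, 1.0, n)
        y = slope * x + 0.2 + rng.normal(0, sd, n)
        fit = fit_linear_calibration(np.column_stack([x, y]))
        se = sd / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(fit.slope - slope) < 3 * se


class TestDepthProfile:
    def test_constant_map_gives_flat_profile(self):
        dmap = _map(np.full((40, 40), 4.5))
        line = [(20, y) for y in range(5, 35)]
        prof = depth_profile(dmap, line, MAG)
        depths = [d for _, d in prof]
        assert np.ptp(depths) == 0.0
        assert depths[0] == pytest.approx(2.0)

    def test_cup_profile_shows_flat_bottom_and_steep_walls(
        self, cup_dmap_desk, cup_scene_desk, desk_cam
    ):
        """A Fig-15-style vertical section: plateau at the cup ground, sharp
        transitions at the walls, rim level matching the generator truth."""
        from scipy.signal import medfilt

        from lffundus.pipeline import scene_papilla_geometry

        geom = scene_papilla_geometry(cup_scene_desk, desk_cam, cup_dmap_desk.resolution)
        cx, cy = geom.center_px
        r = geom.radius_px
        half = int(2.0 * r)
        # pool five parallel vertical lines; per-position medians suppress the
        # occasional wrong-lobe outlier of single-pixel samples
        med_by: dict[int, list[float]] = {}
        for dx in (-4, -2, 0, 2, 4):
            prof = depth_profile(
                cup_dmap_desk,
                [(cx + dx, cy + dy) for dy in range(-half, half + 1)],
                desk_cam.magnification,
            )
            for p, d in prof:
                med_by.setdefault(round(p), []).append(d)
        ps = np.array(sorted(med_by))
        zs = medfilt(np.array([np.median(med_by[p]) for p in ps]), 7)
        center = np.abs(ps - half) < 0.3 * r
        rim = np.abs(ps - half) > 1.6 * r
        plateau = np.median(zs[center])
        rim_lvl = np.median(zs[rim])
        # expected depth step: cup depth minus sphere sag at the rim ring
        mm_map = desk_cam.mm_per_px_object * 4
        w, h = cup_dmap_desk.resolution
        x_mm = (cx - (w - 1) / 2) * mm_map
        truth = np.array(
            [
                cup_scene_desk.depth_mm(x_mm, (cy - half + p - (h - 1) / 2) * mm_map)
                for p in ps
            ]
        )
        expected = np.median(truth[center]) - np.median(truth[rim])
        assert plateau - rim_lvl == pytest.approx(expected, abs=0.08)
        assert np.median(np.abs(zs[center] - plateau)) < 0.04  # flat bottom
        # steep walls: 25-75 % transition within half a papilla radius
        u = (zs - rim_lvl) / (plateau - rim_lvl)
        for side in (ps < half, ps >= half):
            uu = u[side] if side[0] else u[side][::-1]
            pp = ps[side] if side[0] else ps[side][::-1]
            c25 = pp[np.argmax(uu > 0.25)]
            c75 = pp[np.argmax(uu > 0.75)]
            assert abs(c75 - c25) < 0.5 * r

    def test_profile_error_against_generator_truth(
        self, cup_dmap_desk, cup_scene_desk, desk_cam
    ):
        from lffundus.pipeline import scene_papilla_geometry

        geom = scene_papilla_geometry(cup_scene_desk, desk_cam, cup_dmap_desk.resolution)
        cx, cy = geom.center_px
        half = int(2.0 * geom.radius_px)
        mm_map = desk_cam.mm_per_px_object * 4
        w, h = cup_dmap_desk.resolution
        ref = desk_cam.reference_virtual_depth / desk_cam.magnification.axial_mag
        errors = []
        for dx in (-4, -2, 0, 2, 4):
            line = [(cx + dx, cy + dy) for dy in range(-half, half + 1)]
            for p, d in depth_profile(cup_dmap_desk, line, desk_cam.magnification):
                y_map = cy - half + p
                x_mm = (cx + dx - (w - 1) / 2) * mm_map
                y_mm = (y_map - (h - 1) / 2) * mm_map
                errors.append(d - ref - cup_scene_desk.depth_mm(x_mm, y_mm))
        # single-pixel samples keep a heavy tail of wrong-lobe matches that the
        # averaging-circle measurements (not the raw profile) suppress
        assert np.median(np.abs(errors)) < 0.06
        assert np.percentile(np.abs(errors), 90) < 0.25

    def test_point_outside_map_rejected(self):
        dmap = _map(np.full((10, 10), 2.0))
        with pytest.raises(ParameterError):
            depth_profile(dmap, [(5, 5), (5, 20)], MAG)
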
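"""Patch matching, triangulation gates, and the exhaustive-search oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from lffundus.depth_estimation import (
    MatchingParams,
    correlate_patches,
    estimate_depth,
    patch_std,
    preprocess,
)
from lffundus.plenoptic_model import LENS_TYPES
from lffundus.synthetic_data import ParameterError, make_fundus_scene, render_raw_lightfield


def _smooth_noise(shape, sigma, seed):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (img - img.min()) / (img.max() - img.min())


class TestMatchingParams:
    def test_defaults_follow_study_settings(self):
        p = MatchingParams()
        assert p.min_correlation == 0.860
        assert p.min_std_dev == 0.006
        assert p.patch_diameter_px == 5
        assert p.patch_stride_px == 1
        assert p.enabled_lens_types == frozenset(LENS_TYPES)
        assert p.depth_range_pct == (0.0, 130.0)
        assert p.consistency_check is True

    def test_percent_range_maps_onto_v_window(self):
        p = MatchingParams()
        lo, hi = p.effective_v_range
        assert lo == pytest.approx(1.0)
        assert hi == pytest.approx(12.7)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(min_correlation=1.2),
            dict(patch_diameter_px=4),
            dict(patch_stride_px=0),
            dict(depth_range_pct=(50.0, 10.0)),
            dict(enabled_lens_types=frozenset({"nearish"})),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            MatchingParams(**kwargs)

    def test_dict_roundtrip(self):
        p = MatchingParams(min_correlation=0.5, lag_step_px=1.0)
        assert MatchingParams.from_dict(p.to_dict()) == p


class TestPatchStd:
    def test_uniform_patch_is_zero(self):
        img = np.full((20, 20), 777, dtype=np.uint16)
        assert patch_std(img, (10, 10), 5) == 0.0

    def test_balanced_checkerboard_is_half(self):
        img = ((np.indices((16, 16)).sum(axis=0) % 2) * 65535).astype(np.uint16)
        # balanced binary patch: sd is exactly half of full scale
        assert patch_std(img, (8, 8), 4) == pytest.approx(0.5, abs=1e-6)
        # 5x5 patch holds 13 of one value, 12 of the other
        assert patch_std(img, (8, 8), 5) == pytest.approx(
            math.sqrt(13 * 12) / 25, abs=1e-6
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_two_pass_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 65536, size=(15, 15)).astype(np.uint16)
        got = patch_std(img, (7, 7), 5)
        patch = img[5:10, 5:10].astype(float) / 65535.0
        mean = patch.sum() / patch.size
        expected = math.sqrt(((patch - mean) ** 2).sum() / patch.size)
        assert got == pytest.approx(expected, abs=1e-12)


class TestCorrelatePatches:
    def test_integer_shift_recovered(self):
        a = _smooth_noise((60, 80), 1.5, 1)
        b = np.roll(a, shift=-3, axis=1)  # content displaced by -x: lag 3 along +x
        lags, corrs = [], []
        for cy in range(15, 50, 5):
            for cx in range(15, 65, 7):
                lag, corr = correlate_patches(
                    a, b, (cx, cy), (1.0, 0.0), np.arange(1.0, 6.0, 0.5)
                )
                lags.append(lag)
                corrs.append(corr)
        assert np.median(corrs) > 0.99
        assert np.median(lags) == pytest.approx(3.0, abs=0.05)

    def test_uncorrelated_noise_rejected_by_threshold(self):
        rng = np.random.default_rng(0)
        a = rng.random((40, 40))
        b = rng.random((40, 40))
        _, corr = correlate_patches(a, b, (20, 20), (1.0, 0.0), np.arange(1.0, 8.0))
        assert corr < 0.860

    def test_subpixel_shift_from_supersampled_render(self):
        # render at 10x and downsample so B is A shifted by exactly 2.5 px
        hi = _smooth_noise((400, 800), 18.0, 7)
        a = hi[::10, ::10]
        b = hi[::10, 25::10]
        b = b[:, : a.shape[1] - 3]
        lag, corr = correlate_patches(
            a, b, (30, 20), (1.0, 0.0), np.arange(1.0, 5.1, 0.5)
        )
        assert corr > 0.99
        assert lag == pytest.approx(2.5, abs=0.1)

    def test_empty_search_range(self):
        a = _smooth_noise((20, 20), 1.0, 2)
        lag, corr = correlate_patches(a, a, (10, 10), (1.0, 0.0), [])
        assert math.isnan(lag)
        assert corr == -1.0


def _brute_force_points(raw, params):
    """Exhaustive matcher: plain loops over lenses, offsets and lags.

    Independent re-derivation of the matching contract used as oracle: for
    every patch and every lag of the search grid the Pearson correlation is
    computed with ``np.corrcoef``; the same gates, subpixel parabola and
    reverse consistency rule are applied.
    """
    mla = raw.mla
    img = raw.pixels.astype(float) / raw.sensor.full_scale
    d = params.patch_diameter_px
    pr = (d - 1) // 2
    r_foot = mla.pitch_px / 2
    r_contain = r_foot - (pr + 1) * math.sqrt(2.0)
    v_lo, v_hi = params.effective_v_range
    step = params.lag_step_px

    def sample(center):
        oy, ox = np.mgrid[-pr : pr + 1, -pr : pr + 1]
        return ndimage.map_coordinates(
            img,
            [center[1] + oy.ravel(), center[0] + ox.ravel()],
            order=1,
            mode="nearest",
        )

    def pearson(a, b):
        if a.std() == 0 or b.std() == 0:
            return -2.0
        return float(np.corrcoef(a, b)[0, 1])

    def parabola(cl, c0, cr):
        denom = cl - 2 * c0 + cr
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (cl - cr) / denom, -0.5, 0.5))

    kmax = int(math.floor(r_contain))
    us = [
        (ux, uy)
        for uy in range(-kmax, kmax + 1, params.patch_stride_px)
        for ux in range(-kmax, kmax + 1, params.patch_stride_px)
        if math.hypot(ux, uy) <= r_contain
    ]
    qr = {tuple(q): i for i, q in enumerate(map(tuple, mla.axial_qr))}
    enabled = {LENS_TYPES.index(t) for t in params.enabled_lens_types}
    results = {}
    for dq, dr in ((1, 0), (0, 1), (1, -1)):
        for i, (q0, r0) in enumerate(map(tuple, mla.axial_qr)):
            j = qr.get((q0 + dq, r0 + dr))
            if j is None:
                continue
            if mla.lens_type[i] not in enabled or mla.lens_type[j] not in enabled:
                continue
            ci, cj = mla.centers_xy[i], mla.centers_xy[j]
            vec = cj - ci
            b = float(np.linalg.norm(vec))
            unit = vec / b
            lo = max(b / v_hi, step)
            start = math.ceil(lo / step - 1e-9) * step
            lags = np.arange(start, b / v_lo + 1e-9, step)
            for u in us:
                ua = np.asarray(u, dtype=float)
                lags_u = [
                    lag
                    for lag in lags
                    if np.linalg.norm(ua - unit * lag) <= r_contain
                ]
                if not lags_u:
                    continue
                pa = sample(ci + ua)
                corrs = [
                    pearson(pa, sample(cj + ua - unit * lag)) for lag in lags_u
                ]
                k = int(np.argmax(corrs))
                lag_ref = lags_u[k]
                if 0 < k < len(lags_u) - 1 and corrs[k - 1] > -2 and corrs[k + 1] > -2:
                    lag_ref += step * parabola(corrs[k - 1], corrs[k], corrs[k + 1])
                v = b / lag_ref
                pb = sample(cj + ua - unit * lags_u[k])
                if (
                    pa.std() < params.min_std_dev
                    or pb.std() < params.min_std_dev
                    or corrs[k] < params.min_correlation
                    or not v_lo <= v <= v_hi
                ):
                    continue
                if params.consistency_check:
                    u_rev = np.rint(ua - unit * lag_ref)
                    ps = sample(cj + u_rev)
                    valid = [
                        np.linalg.norm(u_rev + unit * lag) <= r_contain for lag in lags
                    ]
                    if not any(valid):
                        continue
                    rcorrs = [
                        pearson(ps, sample(ci + u_rev + unit * lag)) if ok else -3.0
                        for lag, ok in zip(lags, valid)
                    ]
                    kr = int(np.argmax(rcorrs))
                    lag_rev = lags[kr]
                    if (
                        0 < kr < len(lags) - 1
                        and rcorrs[kr - 1] > -2
                        and rcorrs[kr + 1] > -2
                    ):
                        lag_rev += step * parabola(
                            rcorrs[kr - 1], rcorrs[kr], rcorrs[kr + 1]
                        )
                    landing = u_rev + unit * lag_rev
                    if np.linalg.norm(landing - ua) > params.consistency_tol_px:
                        continue
                results[(i, j, u)] = (b / lag_ref, corrs[k])
    return results


@pytest.fixture(scope="module")
def tiny_raw(tiny_cam):
    scene = make_fundus_scene(0.0, seed=31, fundus_radius_mm=1e6)
    return render_raw_lightfield(scene, tiny_cam, noise_sd=0.0, seed=31)


class TestEstimateDepth:
    def test_tiny_instance_has_at_most_seven_lenses(self, tiny_raw):
        assert len(tiny_raw.mla) <= 7

    def test_matches_exhaustive_oracle(self, tiny_raw):
        params = MatchingParams(lag_step_px=1.0)  # integer lag grid
        points = estimate_depth(tiny_raw, params)
        oracle = _brute_force_points(tiny_raw, params)
        centers = tiny_raw.mla.centers_xy
        got = {}
        for x, y, v, corr, i, j in zip(
            points.x_px, points.y_px, points.v, points.correlation,
            points.lens_a, points.lens_b,
        ):
            u = (np.array([x, y]) - centers[i]) / v
            got[(int(i), int(j), (int(round(u[0])), int(round(u[1]))))] = (v, corr)
        assert set(got) == set(oracle)
        for key in oracle:
            assert got[key][0] == pytest.approx(oracle[key][0], abs=1e-9)
            assert got[key][1] == pytest.approx(oracle[key][1], abs=1e-9)

    def test_uniform_raw_yields_no_points(self, tiny_cam):
        scene = make_fundus_scene(
            0.0, seed=5, fundus_radius_mm=1e6, n_vessels=0,
            papilla_radius_mm=0.01, papilla_center_mm=(2.0, 1.5),
        )
        scene._speckle = np.zeros_like(scene._speckle)
        scene._choroid = np.zeros_like(scene._choroid)
        raw = render_raw_lightfield(scene, tiny_cam, noise_sd=0.0, seed=5)
        assert len(estimate_depth(raw)) == 0

    def test_constant_depth_median_within_2_percent(self, flat_points_mini, mini_cam):
        v_true = mini_cam.reference_virtual_depth
        assert len(flat_points_mini) > 100
        assert abs(np.median(flat_points_mini.v) - v_true) / v_true < 0.02

    def test_monotone_gating(self, flat_raw_mini):
        loose = estimate_depth(flat_raw_mini, MatchingParams(min_correlation=0.5))
        strict = estimate_depth(flat_raw_mini, MatchingParams(min_correlation=0.95))

        def keys(p):
            return set(zip(p.lens_a, p.lens_b, np.round(p.x_px, 4), np.round(p.y_px, 4)))

        assert keys(strict) <= keys(loose)
        assert np.all(strict.correlation >= 0.95)

    def test_two_plane_scene_separates_v_modes(self, mini_cam):
        # flat surround + flat-bottomed cup = two depth planes
        scene = make_fundus_scene(
            0.4, seed=41, fundus_radius_mm=1e6, papilla_radius_mm=0.45,
            papilla_center_mm=(0.0, 0.0),
        )
        raw = render_raw_lightfield(scene, mini_cam, noise_sd=0.0, seed=41)
        pts = estimate_depth(raw)
        mm = mini_cam.mm_per_px_object
        W, H = mini_cam.sensor.width_px, mini_cam.sensor.height_px
        r_px = (pts.x_px - (W - 1) / 2) ** 2 + (pts.y_px - (H - 1) / 2) ** 2
        inner = r_px < (0.45 * 0.55 / mm) ** 2
        outer = r_px > (0.60 / mm) ** 2
        assert inner.sum() > 30 and outer.sum() > 30
        sep = np.median(pts.v[inner]) - np.median(pts.v[outer])
        expected = mini_cam.magnification.axial_mag * 0.4
        assert sep == pytest.approx(expected, rel=0.03)

    def test_no_enabled_lens_types_rejected(self, flat_raw_mini):
        with pytest.raises(ParameterError):
            estimate_depth(flat_raw_mini, MatchingParams(enabled_lens_types=frozenset()))

    def test_points_respect_gates(self, flat_points_mini):
        p = MatchingParams()
        assert np.all(flat_points_mini.correlation >= p.min_correlation)
        lo, hi = p.effective_v_range
        assert np.all((flat_points_mini.v >= lo) & (flat_points_mini.v <= hi))

    def test_preprocess_is_identity(self, flat_raw_mini):
        assert preprocess(flat_raw_mini) is flat_raw_mini

    def test_csv_export_roundtrip(self, flat_points_mini, tmp_path):
        path = tmp_path / "points.csv"
        flat_points_mini.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["x_px", "y_px", "v", "correlation", "lens_a", "lens_b"]
        assert len(df) == len(flat_points_mini)
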